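"""Forward simulators: mass balance, determinism, regime behaviour, inversion."""

import numpy as np
import pytest

from ringrelease.accounting import (
    biphasic_protocol,
    daily_protocol,
    reconstruct_biphasic,
    reconstruct_monophasic,
)
from ringrelease.assessment import MediumSpec
from ringrelease.errors import ValidationError
from ringrelease.reference import DAPIVIRINE, IPA_WATER_SOLUBILITY
from ringrelease.release_models import (
    eval_higuchi,
    eval_zero_order,
    fit_higuchi,
    select_time_basis,
)
from ringrelease.synthetic_data import (
    AnomalySpec,
    BiphasicConfig,
    HiguchiLaw,
    MonophasicConfig,
    invert_to_concentrations,
    simulate_biphasic,
    simulate_monophasic,
)


def mono_config(drug, protocol, solubility, *, a=2022.0, burst=0.0, noise=0.0,
                n_rep=1, seed=0, phi=0.5, anomaly=None, label="medium"):
    return MonophasicConfig(
        drug=drug,
        medium=MediumSpec(label, solubility=solubility, volume=100.0),
        protocol=protocol,
        law=HiguchiLaw(a=a, burst=burst),
        saturation_fraction=phi,
        noise_cv=noise,
        n_replicates=n_rep,
        seed=seed,
        anomaly=anomaly,
    )


def biph_config(drug, protocol, **kw):
    medium = MediumSpec("acetate_pH4.2", solubility=0.499, volume=100.0, pH=4.2)
    defaults = dict(drug=drug, buffer_medium=medium, protocol=protocol,
                    noise_cv=0.0, n_replicates=1, seed=0)
    defaults.update(kw)
    return BiphasicConfig(**defaults)


class TestSimulateMonophasic:
    def test_solubility_cap_gives_exactly_linear_release(self, drug, protocol_daily):
        """When phi*S*V is below the matrix increment every day, daily amounts
        are constant at the cap and cumulative release is linear."""
        S = IPA_WATER_SOLUBILITY["0/100"]
        res = simulate_monophasic(mono_config(drug, protocol_daily, S))
        cap = 0.5 * S * 100.0
        amounts = np.diff(np.concatenate([[0.0], res.true_cumulative[0]]))
        assert amounts == pytest.approx(np.full(28, cap), rel=1e-12)

    def test_uncapped_roundtrip_recovers_higuchi_parameters(self, drug, protocol_daily):
        a, b = 2022.0, 150.0
        res = simulate_monophasic(
            mono_config(drug, protocol_daily, IPA_WATER_SOLUBILITY["50/50"],
                        a=a, burst=b)
        )
        prof = reconstruct_monophasic(res.series[0], protocol_daily)
        fit = fit_higuchi(prof)
        assert fit.slope == pytest.approx(a, rel=1e-9)
        assert fit.intercept == pytest.approx(b, rel=1e-9)

    def test_noise_free_replicates_identical(self, drug, protocol_daily):
        res = simulate_monophasic(
            mono_config(drug, protocol_daily, 645.0, n_rep=4)
        )
        for s in res.series[1:]:
            assert s.concentrations == pytest.approx(
                res.series[0].concentrations, abs=0
            )

    def test_seeded_determinism(self, drug, protocol_daily):
        kw = dict(noise=0.03, n_rep=4, seed=42)
        a = simulate_monophasic(mono_config(drug, protocol_daily, 645.0, **kw))
        b = simulate_monophasic(mono_config(drug, protocol_daily, 645.0, **kw))
        for sa, sb in zip(a.series, b.series):
            assert np.array_equal(sa.concentrations, sb.concentrations)

    def test_reconstruction_matches_truth(self, drug, protocol_weekend):
        """Noise-free reconstruct(simulate(...)) reproduces the simulator's
        cumulative release to well under 0.1% at every time."""
        res = simulate_monophasic(
            mono_config(drug, protocol_weekend, 24.14, a=1693.0, burst=50.0)
        )
        prof = reconstruct_monophasic(res.series[0], protocol_weekend)
        assert prof.cumulative == pytest.approx(res.true_cumulative[0], rel=1e-9)

    def test_loading_conservation(self, drug, protocol_daily):
        with pytest.warns(UserWarning, match="truncat"):
            res = simulate_monophasic(
                mono_config(drug, protocol_daily, 645.0, a=5000.0, burst=1000.0)
            )
        assert res.true_cumulative[0][-1] <= drug.ring_loading * (1 + 1e-12)

    def test_exhaustion_truncates_with_warning(self, protocol_daily, drug):
        from dataclasses import replace

        tiny = replace(drug, ring_loading=500.0)
        with pytest.warns(UserWarning, match="truncat"):
            res = simulate_monophasic(
                mono_config(tiny, protocol_daily, 645.0, a=2022.0)
            )
        assert res.true_cumulative[0][-1] == pytest.approx(500.0)

    def test_regime_switches_across_solubility_ladder(self, drug, protocol_daily):
        """As medium solubility rises through the measured ladder, the best
        time basis flips from zero-order (capped) to Higuchi (matrix)."""
        bases = []
        for label in ("0/100", "10/90", "20/80", "30/70", "40/60", "50/50"):
            res = simulate_monophasic(
                mono_config(drug, protocol_daily, IPA_WATER_SOLUBILITY[label])
            )
            prof = reconstruct_monophasic(res.series[0], protocol_daily)
            bases.append(select_time_basis(prof).basis)
        assert bases[0] == "zero_order"
        assert bases[-1] == "higuchi"
        switched = bases.index("higuchi")
        assert all(b == "higuchi" for b in bases[switched:])


class TestSimulateBiphasic:
    def test_mass_balance_within_contract(self, drug, protocol_biphasic):
        res = simulate_biphasic(biph_config(drug, protocol_biphasic, n_replicates=2))
        for rep in res.replicates:
            assert rep.mass_balance_drift() <= 1e-3

    def test_sampling_correction_recovers_phase_totals(self, drug, protocol_biphasic):
        """Reconstructed buffer + octanol cumulative equals ring release."""
        res = simulate_biphasic(biph_config(drug, protocol_biphasic))
        rep = res.replicates[0]
        pb = reconstruct_biphasic(rep.buffer, protocol_biphasic)
        po = reconstruct_biphasic(rep.octanol, protocol_biphasic)
        assert pb.cumulative + po.cumulative == pytest.approx(rep.released, rel=1e-9)

    def test_no_transfer_keeps_octanol_empty(self, drug, protocol_biphasic):
        res = simulate_biphasic(biph_config(drug, protocol_biphasic, q_t=0.0))
        rep = res.replicates[0]
        assert np.all(rep.octanol.concentrations == 0.0)
        # buffer approaches saturation S_aq * V_b = 49.9 µg
        assert rep.in_buffer[-1] == pytest.approx(0.499 * 100.0, rel=0.02)

    def test_equilibrium_ratio_approaches_distribution_coefficient(self, drug):
        """With no ring source and no sampling, C_o/C_b -> D."""
        prot = biphasic_protocol(40, sample_volume=0.0)
        cfg = biph_config(
            drug, prot, k_r=0.0, q_t=50.0, distribution_ratio=5.0,
            initial_buffer_amount=1000.0,
        )
        rep = simulate_biphasic(cfg).replicates[0]
        ratio = rep.octanol.concentrations[-1] / rep.buffer.concentrations[-1]
        assert ratio == pytest.approx(5.0, rel=0.01)

    def test_acidic_buffer_accumulates_more_than_neutral(self, drug, protocol_biphasic):
        acid = simulate_biphasic(biph_config(drug, protocol_biphasic))
        neutral_medium = MediumSpec("phosphate_pH7", solubility=0.018,
                                    volume=100.0, pH=7.0)
        neutral = simulate_biphasic(
            biph_config(drug, protocol_biphasic, buffer_medium=neutral_medium)
        )
        assert (acid.replicates[0].in_octanol[-1]
                > neutral.replicates[0].in_octanol[-1])

    def test_anomalous_ring_diverges_in_octanol(self, drug, protocol_biphasic):
        cfg = biph_config(
            drug, protocol_biphasic, n_replicates=4,
            anomaly=AnomalySpec(replicate=3, start_day=10.0, jump_rate=200.0),
        )
        res = simulate_biphasic(cfg)
        clean = res.replicates[0].octanol.concentrations
        bad = res.replicates[3].octanol.concentrations
        assert bad[:9] == pytest.approx(clean[:9], rel=1e-9)
        assert bad[-1] > clean[-1] * 2
        # mass balance still holds with the artefact source included
        assert res.replicates[3].mass_balance_drift() <= 1e-3

    def test_seeded_determinism(self, drug, protocol_biphasic):
        cfg = biph_config(drug, protocol_biphasic, noise_cv=0.03, n_replicates=2,
                          seed=9)
        a = simulate_biphasic(cfg)
        b = simulate_biphasic(cfg)
        for ra, rb in zip(a.replicates, b.replicates):
            assert np.array_equal(ra.buffer.concentrations, rb.buffer.concentrations)
            assert np.array_equal(ra.octanol.concentrations, rb.octanol.concentrations)


class TestInvertToConcentrations:
    def test_constant_target_recurrence(self):
        """f = V*c0 constant: first concentration c0, then the sequence that
        keeps V*C_n + sum v_s*C_i constant (hand recurrence, 3 events)."""
        prot = biphasic_protocol(3, octanol_volume=20.0)
        c0 = 5.0
        series = invert_to_concentrations(lambda t: 20.0 * c0, prot, phase="octanol")
        # hand solution: C1 = 5; C2 = (100-5)/20 = 4.75; C3 = (100-9.75)/20
        assert series.concentrations == pytest.approx([5.0, 4.75, 4.5125])

    def test_full_replacement_increments(self, protocol_daily):
        f = lambda t: eval_higuchi(t, 1000.0, 0.0)
        series = invert_to_concentrations(f, protocol_daily)
        prof = reconstruct_monophasic(series, protocol_daily)
        assert prof.cumulative == pytest.approx(f(prof.times), rel=1e-12)

    def test_biphasic_roundtrip_identity(self):
        prot = biphasic_protocol(28)
        f = lambda t: eval_zero_order(t, 40.94, -26.24).clip(min=0)
        series = invert_to_concentrations(f, prot, phase="octanol")
        prof = reconstruct_biphasic(series, prot)
        assert prof.cumulative == pytest.approx(f(prof.times), rel=1e-12)

    def test_negative_early_values_clamped(self, protocol_daily):
        # zero-order line with negative intercept: clamped to zero at start
        f = lambda t: eval_zero_order(t, 10.0, -25.0)
        series = invert_to_concentrations(f, protocol_daily)
        assert series.concentrations[0] == 0.0
        assert series.concentrations[1] == 0.0
        assert np.all(series.concentrations >= 0)

    def test_decreasing_target_rejected(self, protocol_daily):
        with pytest.raises(ValidationError):
            invert_to_concentrations(lambda t: -t, protocol_daily,
                                     clamp_negative=False)
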