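"""Shared test helpers."""

import numpy as np

from ringrelease.accounting import ReleaseProfile

DAYS = np.arange(1.0, 29.0)


def profile_from_cumulative(cumulative, rid="r1", times=DAYS, fractional=None):
    """Build a ReleaseProfile directly from a cumulative release curve."""
    cum = np.asarray(cumulative, dtype=float)
    t = np.asarray(times, dtype=float)
    inter = np.diff(np.concatenate([[0.0], cum]))
    lengths = np.diff(np.concatenate([[0.0], t]))
    return ReleaseProfile(rid, t, inter, cum, lengths, fractional=fractional)
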