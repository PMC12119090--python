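"""Small numeric helpers shared across modules."""

from __future__ import annotations

import warnings

import numpy as np


def nanmean_quiet(a, axis=None):
    """np.nanmean that treats all-NaN slices as NaN without warning."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=axis)


def nanstd_quiet(a, axis=None, ddof=0):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(a, axis=axis, ddof=ddof)
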