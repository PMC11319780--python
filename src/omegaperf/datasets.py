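"""Bundled reliability datasets used in the worked examples.

Two classical data sets:

* HPLC — concentrations from 56 blood samples of organ transplant recipients
  analysed by high-performance liquid chromatography.  The analysis scales
  each observation by the maximum, 980.  The progressively censored version
  observes m = 24 failures out of n = 56 with removal scheme
  (7, 4*2, 0*2, 3, 0*7, 1, 5, 2, 0*2, 3*2, 0*4).

  The raw listing (``hplc_full``) is a reconstruction from a corrupted source
  table — see the synthetic-fixture note in its docstring entry below.

* Ball bearing — millions of revolutions to failure for 23 ball bearings
  (Lawless).  The censored version observes m = 11 of n = 23 with removal
  scheme (0*3, 3, 2, 3, 1, 0*3, 3) applied to the data scaled by the
  maximum, 1.2792.
"""

from __future__ import annotations

import numpy as np

from .censoring import CensoredSample, CensoringScheme, parse_removals

__all__ = ["load_fixture", "FIXTURE_NAMES"]

# Reconstructed HPLC listing (synthetic fixture): the available rendering of
# the source table concatenates all digits, so the 56 raw values below were
# recovered by constrained segmentation — every value an integer <= 980, none
# below the first observed failure, containing the 24 progressively censored
# observations — and validated against the published Kolmogorov-Smirnov
# statistic of the Omega fit (0.0919683; this listing reproduces 0.0919678).
_HPLC_RAW = [
    99, 327, 203, 241, 578, 153, 109, 156, 93, 244, 245, 71, 151, 271,
    125, 275, 350, 521, 370, 166, 402, 35, 77, 428, 185, 112, 206, 130,
    127, 285, 221, 336, 339, 129, 318, 159, 104, 198, 254, 280, 266, 653,
    109, 298, 440, 340, 162, 227, 556, 118, 159, 980, 346, 118, 148, 87,
]

# Progressively censored HPLC sample, times already scaled by 980.
_HPLC_CENSORED_TIMES = [
    0.036, 0.111, 0.129, 0.156, 0.159, 0.162, 0.189, 0.202,
    0.207, 0.210, 0.226, 0.232, 0.246, 0.249, 0.259, 0.324,
    0.346, 0.347, 0.353, 0.437, 0.567, 0.589, 0.666, 1.0,
]
_HPLC_REMOVALS = parse_removals("7,4*2,0*2,3,0*7,1,5,2,0*2,3*2,0*4")

# Millions of revolutions to failure of 23 ball bearings.
_BALLBEARING = [
    0.1788, 0.2892, 0.3300, 0.4152, 0.4212, 0.4560, 0.4848, 0.5184,
    0.5196, 0.5412, 0.5556, 0.6780, 0.6780, 0.6780, 0.6864, 0.6864,
    0.6888, 0.8412, 0.9312, 0.9864, 1.0512, 1.0584, 1.2792,
]

# Progressively censored ball-bearing sample, times scaled by 1.2792.  The
# removal scheme is the compact form stated with the data; it is the only
# scheme consistent with both the full listing and the censored times.
_BALLBEARING_CENSORED_TIMES = [
    0.139775, 0.226079, 0.257974, 0.324578, 0.405253, 0.434334,
    0.536585, 0.538462, 0.657598, 0.727955, 0.771107,
]
_BALLBEARING_REMOVALS = parse_removals("0*3,3,2,3,1,0*3,3")

FIXTURE_NAMES = (
    "hplc_full",
    "hplc_censored",
    "ballbearing_full",
    "ballbearing_censored",
)


def load_fixture(name: str):
    """Return a bundled dataset by name.

    ``hplc_censored`` and ``ballbearing_censored`` return
    :class:`~omegaperf.censoring.CensoredSample`; ``hplc_full`` and
    ``ballbearing_full`` return the complete listings as numpy arrays.
    """
    if name == "hplc_full":
        return np.asarray(_HPLC_RAW, dtype=float)
    if name == "hplc_censored":
        m = len(_HPLC_CENSORED_TIMES)
        n = m + sum(_HPLC_REMOVALS)
        return CensoredSample(
            CensoringScheme(n, m, _HPLC_REMOVALS), _HPLC_CENSORED_TIMES
        )
    if name == "ballbearing_full":
        return np.asarray(_BALLBEARING, dtype=float)
    if name == "ballbearing_censored":
        m = len(_BALLBEARING_CENSORED_TIMES)
        n = m + sum(_BALLBEARING_REMOVALS)
        return CensoredSample(
            CensoringScheme(n, m, _BALLBEARING_REMOVALS),
            _BALLBEARING_CENSORED_TIMES,
        )
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
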