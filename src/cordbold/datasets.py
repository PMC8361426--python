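"""Packaged reference tables."""

from importlib import resources

import pandas as pd

MJOA_SUBSCALE_MAXIMA = {
    "mjoa_upper_motor": 5,
    "mjoa_lower_motor": 7,
    "mjoa_upper_sensory": 3,
    "mjoa_bladder": 3,
}
MJOA_TOTAL_MAX = 18


def load_dcm_cohort() -> pd.DataFrame:
    """Demographic and clinical table of the 23-patient DCM cohort.

    One row per patient: age (years), sex, vertebral site of impairment,
    duration of symptoms (months), the four mJOA subscores and the 18-point
    total. Compression-volume and activation columns are *not* part of this
    table; they are produced by the imaging stages (or by
    :func:`cordbold.synth.make_cohort` for synthetic cohorts).
    """
    ref = resources.files("cordbold.data").joinpath("dcm_cohort.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)
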