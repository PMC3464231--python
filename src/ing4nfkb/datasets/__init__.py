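"""Small bundled reference tables.

These are the published summary counts from the breast-tumor TMA study
this pipeline models (marker-call counts per clinical subgroup, the
pathology cross-tabulations, lymph-node status by ING4/p-p65 call) and
the three-gene PMA-induction folds measured by RT-qPCR in the control
and ING4-overexpressing T47D lines. They serve as desk-scale inputs for
the contingency and signature-derivation stages; no raw patient-level
data is included or needed.
"""

from importlib import resources

import pandas as pd

__all__ = [
    "load_tma_marker_counts",
    "load_tma_pathology_counts",
    "load_tma_ln_counts",
    "load_pma_induction_folds",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t")


def load_tma_marker_counts() -> pd.DataFrame:
    """ING4 low/high counts per clinical subgroup (n = 227 tumors)."""
    return _read("tma_marker_counts.tsv")


def load_tma_pathology_counts() -> pd.DataFrame:
    """ING4 low/high counts per pathologic feature, with the published
    display percentages alongside."""
    return _read("tma_pathology_counts.tsv")


def load_tma_ln_counts() -> pd.DataFrame:
    """Lymph-node status counts by joint ING4 / p-p65 call (n = 103)."""
    return _read("tma_ln_counts.tsv")


def load_pma_induction_folds() -> pd.DataFrame:
    """RT-qPCR PMA-induction folds for IL6/IL8/PTGS2 in the control and
    ING4-overexpressing lines."""
    return _read("pma_induction_folds.tsv")
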