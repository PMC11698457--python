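"""Bundled worked-example tables from the Artabotrys sumatranus leaf-extract study.

The study screened 30 leaf extracts (five ethanol/water solvent mixtures,
six replicates) against alpha-glucosidase inhibition and DPPH antioxidant
assays and published the two branch consensus lists — features that survived
frequency voting in the multivariate-statistical branch and in the machine-
learning branch — together with compound annotations for the final
intersection.  These small tables let the consensus stage be exercised end
to end on real published numbers; the underlying 30 x 80 response matrix and
per-sample IC50 values were not deposited and are not available here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_stat_branch() -> pd.DataFrame:
    """Statistical-branch consensus list: var_id, m/z, appearance percentage."""
    return _read("stat_branch_consensus.csv")


def load_ml_branch() -> pd.DataFrame:
    """ML-branch consensus list: var_id, m/z, appearance percentage."""
    return _read("ml_branch_consensus.csv")


def load_annotations() -> pd.DataFrame:
    """Compound identifications (where available) for the final candidates."""
    return _read("compound_annotations.csv")


def load_case_study_activities():
    """Per-sample IC50 values of the case study.

    The study's per-sample IC50 table was published only as a PDF supplement
    and is not redistributable here in data form, so the activity
    cross-correlation of the case study cannot be recomputed; only its
    published 4x4 matrix is known.
    """
    raise FileNotFoundError(
        "per-sample IC50 values for the case study are not available in data "
        "form; supply your own activity CSV via data_model.load_activity_table"
    )
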