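"""Packaged datasets.

``load_binding_activity_table`` returns the thermodynamic and activity
constants of the S2-derived peptide variant library binding to full-length
SlyD (two sites: chaperone/IF and catalytic/FKBP) and to the IF-deleted
construct.  Missing measurements ("n.d.") are NaN.

``load_synthetic_conformation_refs`` returns a synthetic labelled reference
table of inter-domain (d, delta) centroids for the conformational-state
classifier; it is a constructed stand-in, not measured from deposited
structures.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_binding_activity_table",
    "load_synthetic_conformation_refs",
]


def _data_path(name: str):
    return resources.files("prolylkin.data").joinpath(name)


def load_binding_activity_table() -> pd.DataFrame:
    """Peptide-variant binding and activity table.

    Columns
    -------
    variant : peptide variant name (psWT and point mutants thereof)
    kd_if_uM, dh_if_kcal_mol : IF (chaperone) site K_D and binding enthalpy
    kd_fkbp_uM, dh_fkbp_kcal_mol : FKBP (catalytic) site K_D and enthalpy
    activity_wt_per_uM_s : kcat/KM of full-length SlyD, uM^-1 s^-1
    kd_dif_uM, dh_dif_kcal_mol : single-site constants of the IF-deleted
        construct
    activity_dif_per_uM_s : kcat/KM of the IF-deleted construct
    dh_sum_kcal_mol : derived column, dh_if + dh_fkbp (total binding
        enthalpy of the two full-length sites)
    """
    with _data_path("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    df["dh_sum_kcal_mol"] = df["dh_if_kcal_mol"] + df["dh_fkbp_kcal_mol"]
    return df


def load_synthetic_conformation_refs() -> pd.DataFrame:
    """Synthetic labelled (d, delta) reference centroids (see module note)."""
    with _data_path("synthetic_conformation_refs.csv").open() as fh:
        return pd.read_csv(fh, comment="#")
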