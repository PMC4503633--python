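"""Packaged reference constants.

Two small tables travel with the package:

* ``unfolded_reference_table`` -- per-amino-acid conformational entropies
  of residues representative of the unfolded state (kB units, relative to
  the uniform torsion-angle distribution), with N-terminal and C-terminal
  variants (one backbone angle fewer) and a separate row for cysteines in
  disulfide bridges.  Average nearest-neighbor distances (degrees) and
  sample counts are carried along.
* ``oppa_reference_table`` -- rotational and translational binding
  entropies (kB) of 20 lysine-flanked tripeptides bound to the
  oligopeptide-binding protein OppA, by both the nearest-neighbor and the
  histogram estimator, with mean nearest-neighbor distances (rad / A).

Also here: a Bondi-style van der Waals radius lookup used by the
contact-cluster analysis.
"""

from __future__ import annotations

import io
import math

import numpy as np
import pandas as pd

from .estimators import KB_KCAL_PER_MOL_K

__all__ = [
    "unfolded_reference_table",
    "unfolded_reference_entropy",
    "oppa_reference_table",
    "oppa_mean_binding_entropy",
    "vdw_radius",
    "UNFOLDED_REFERENCE_TSV",
    "OPPA_REFERENCE_TSV",
]

# Entropy / av. dist. for internal, N-terminal and C-terminal residue
# variants; av. dist. in degrees.  CYS_SS is the disulfide-bridged
# cysteine row (phi, psi, chi1 torsion set).
UNFOLDED_REFERENCE_TSV = """\
aa\tentropy\tav_dist\tentropy_nterm\tav_dist_nterm\tentropy_cterm\tav_dist_cterm\tcounts
ALA\t-2.4\t0.5\t-0.6\t0.0\t-1.0\t0.0\t23859
CYS\t-4.7\t15.0\t-3.1\t9.2\t-3.3\t8.5\t845
CYS_SS\t-3.6\t4.7\t-2.1\t1.5\t-2.3\t1.3\t3250
ASP\t-4.5\t5.5\t-2.7\t2.6\t-2.9\t2.4\t27673
GLU\t-5.2\t11.3\t-3.5\t7.4\t-4.0\t6.7\t19087
PHE\t-4.9\t7.0\t-3.2\t3.6\t-3.7\t3.1\t11603
GLY\t-1.9\t0.5\t-0.4\t0.0\t-0.5\t0.0\t43795
HIS\t-4.4\t8.5\t-2.7\t4.6\t-3.1\t4.0\t8991
ILE\t-6.6\t4.8\t-4.9\t2.3\t-4.9\t2.2\t12908
LYS\t-7.5\t16.8\t-6.0\t12.5\t-6.3\t11.6\t18930
LEU\t-6.3\t4.5\t-4.6\t2.1\t-5.2\t1.8\t22763
MET\t-6.1\t14.7\t-4.5\t10.1\t-4.9\t9.1\t4848
ASN\t-4.7\t6.6\t-3.0\t3.3\t-3.1\t3.1\t20987
PRO\t-0.8\t0.0\t-0.8\t0.0\t0.0\t0.0\t27620
GLN\t-5.5\t13.7\t-3.9\t9.3\t-4.4\t8.3\t11567
ARG\t-6.9\t18.2\t-5.3\t13.6\t-5.7\t12.7\t15776
SER\t-4.6\t8.0\t-3.0\t4.2\t-3.2\t3.9\t10053
THR\t-5.1\t7.2\t-3.4\t3.7\t-3.6\t3.5\t8829
VAL\t-4.6\t2.2\t-3.0\t0.5\t-3.0\t0.5\t17243
TRP\t-4.8\t9.2\t-3.1\t5.1\t-4.1\t23.5\t4332
TYR\t-5.4\t17.2\t-3.9\t12.0\t-4.2\t10.9\t3550
"""

# Rot./transl. binding entropies of 20 OppA-bound tripeptides, by the
# nearest-neighbor (nn) and histogram (hist) estimators, with the mean
# nearest-neighbor distance columns (rad; angstrom).
OPPA_REFERENCE_TSV = """\
peptide\trot_nn\trot_hist\trot_av_dist\ttrans_nn\ttrans_hist\ttrans_av_dist
KAK\t-8.17\t-8.44\t0.017\t-8.81\t-8.84\t0.04
KCK\t-8.73\t-8.74\t0.014\t-9.03\t-9.00\t0.04
KDK\t-8.34\t-8.45\t0.016\t-9.11\t-9.14\t0.03
KEK\t-8.76\t-8.73\t0.014\t-9.17\t-9.17\t0.03
KFK\t-8.83\t-8.90\t0.014\t-9.10\t-9.17\t0.03
KGK\t-8.09\t-8.33\t0.018\t-8.40\t-8.56\t0.04
KHK\t-8.85\t-8.94\t0.013\t-9.31\t-9.29\t0.03
KIK\t-7.62\t-8.01\t0.020\t-7.98\t-8.22\t0.05
KKK\t-8.99\t-8.98\t0.013\t-9.36\t-9.26\t0.03
KLK\t-8.04\t-8.08\t0.018\t-7.92\t-8.16\t0.05
KMK\t-8.68\t-8.77\t0.014\t-9.14\t-9.15\t0.03
KNK\t-8.40\t-8.48\t0.016\t-9.04\t-8.98\t0.04
KPK\t-8.55\t-8.64\t0.015\t-9.28\t-9.26\t0.03
KQK\t-8.68\t-8.78\t0.015\t-9.12\t-9.11\t0.03
KRK\t-9.00\t-8.89\t0.013\t-9.64\t-9.48\t0.03
KSK\t-8.30\t-8.53\t0.016\t-8.86\t-8.84\t0.04
KTK\t-8.63\t-8.82\t0.015\t-8.98\t-8.98\t0.04
KVK\t-8.86\t-8.90\t0.014\t-9.33\t-9.16\t0.03
KWK\t-8.90\t-8.92\t0.013\t-9.27\t-9.17\t0.03
KYK\t-8.71\t-8.76\t0.014\t-8.90\t-8.85\t0.04
"""

# Bondi van der Waals radii by element, angstrom.
_VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
_VDW_DEFAULT = 1.70


def unfolded_reference_table() -> pd.DataFrame:
    """The unfolded-state reference entropies as a DataFrame indexed by residue."""
    return pd.read_csv(io.StringIO(UNFOLDED_REFERENCE_TSV), sep="\t", index_col="aa")


def unfolded_reference_entropy(residue_type: str, variant: str = "internal") -> float:
    """Unfolded-state reference entropy (kB) for one residue type.

    ``variant`` is one of internal / nterm / cterm; disulfide-bridged
    cysteines use residue type ``CYS_SS``.
    """
    table = unfolded_reference_table()
    key = residue_type.upper()
    if key not in table.index:
        raise KeyError(f"no unfolded reference entropy for residue type {residue_type!r}")
    column = {"internal": "entropy", "nterm": "entropy_nterm", "cterm": "entropy_cterm"}
    if variant not in column:
        raise ValueError(f"unknown variant {variant!r}")
    return float(table.loc[key, column[variant]])


def oppa_reference_table() -> pd.DataFrame:
    return pd.read_csv(io.StringIO(OPPA_REFERENCE_TSV), sep="\t", index_col="peptide")


def oppa_mean_binding_entropy(temperature: float = 300.0) -> dict[str, float]:
    """Average rototranslational binding entropy over the 20 OppA tripeptides.

    Returns the mean nearest-neighbor rotational and translational
    entropies (kB), their sum, and the corresponding -T*dS in kcal/mol.
    """
    table = oppa_reference_table()
    mean_rot = float(table["rot_nn"].mean())
    mean_trans = float(table["trans_nn"].mean())
    total = mean_rot + mean_trans
    return {
        "mean_rot_kB": mean_rot,
        "mean_trans_kB": mean_trans,
        "mean_total_kB": total,
        "minus_T_dS_kcal_mol": -total * KB_KCAL_PER_MOL_K * temperature,
    }


def vdw_radius(element: str) -> float:
    """Van der Waals radius (angstrom) for an element symbol."""
    return _VDW_RADII.get(element.strip().upper(), _VDW_DEFAULT)
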