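"""Published validation-cohort tables for the tag panels this tool targets.

The tag panels were validated on 960 field-collected *An. gambiae* and
*An. coluzzii* from Burkina Faso, karyotyped cytogenetically and genotyped
on both molecular platforms.  This module encodes the published summary
tables of that cohort so that the cross-table identities and worked examples
can be recomputed without access to the per-specimen records:

* ``CLASS_TABLES`` — per inversion, the 3x3 cytogenetic-class x joint
  molecular-class counts for specimens where both molecular methods agreed
  (rows: cytogenetic genotype 0/1/2; columns: shared molecular genotype).
  The heterozygote-rich 2Rj table was not published (discordance there was
  negligible) and is absent.
* ``N_ASSAYED`` — per inversion, specimens successfully genotyped by all
  three methods.
* ``PARITY`` — cohort margins for the odd/even specimen-code analysis: of
  the specimens assayed by both molecular methods, 280 carried odd and 677
  even numeric codes, and 169 of the 170 combined 2La/2Rb/2Ru
  cytogenetic-vs-molecular discordances fell in even-coded specimens.
* ``GTSEQ_TAG_COUNTS`` / ``OA_TAG_COUNTS`` — final tag counts per inversion
  for the sequencing and array panels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CLASS_TABLES: dict[str, np.ndarray] = {
    "2La": np.array([[1, 0, 0], [0, 80, 2], [1, 70, 794]]),
    "2Rb": np.array([[124, 1, 7], [1, 491, 9], [7, 16, 249]]),
    "2Rd": np.array([[389, 7, 0], [7, 31, 0], [0, 0, 0]]),
    "2Ru": np.array([[778, 39, 10], [7, 84, 0], [0, 0, 8]]),
    "2Rc_col": np.array([[153, 7, 0], [10, 235, 0], [0, 1, 95]]),
    "2Rc_gam": np.array([[309, 1, 0], [34, 43, 0], [4, 0, 0]]),
}

N_ASSAYED: dict[str, int] = {
    "2La": 948,
    "2Rj": 435,
    "2Rb": 948,
    "2Rc_col": 513,
    "2Rc_gam": 435,
    "2Rd": 435,
    "2Ru": 948,
}

PARITY = {
    "n_odd": 280,
    "n_even": 677,
    "n_discordant": 170,
    "n_even_discordant": 169,
    "inversions": ("2La", "2Rb", "2Ru"),
}

GTSEQ_TAG_COUNTS: dict[str, int] = {
    "2La": 22,
    "2Rj": 17,
    "2Rb": 22,
    "2Rc_col": 23,
    "2Rc_gam": 13,
    "2Ru": 17,
    "2Rd": 17,
}

OA_TAG_COUNTS: dict[str, int] = {
    "2La": 8,
    "2Rj": 6,
    "2Rb": 10,
    "2Rc_col": 11,
    "2Rc_gam": 3,
    "2Ru": 6,
    "2Rd": 9,
}


def calls_from_class_tables(
    tables: dict[str, np.ndarray] | None = None,
    n_assayed: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Expand the published class tables into per-record triplicate calls.

    Each 3x3 cell (cyt=i, molecular=j) with count c becomes c records with
    ``cyt=i, oa=j, gt=j`` (both molecular methods agree by construction).
    When ``n_assayed`` exceeds an inversion's table total, the remainder —
    complete triples in which the molecular methods disagreed — is padded as
    records where cytogenetics and sequencing agree but the array differs,
    preserving the complete-case denominator without attributing the split
    among the disagreement categories.  Numeric codes are synthetic.
    """
    tables = CLASS_TABLES if tables is None else tables
    rows = []
    code = 0
    for inv, table in tables.items():
        table = np.asarray(table)
        for cyt in range(3):
            for mol in range(3):
                for _ in range(int(table[cyt, mol])):
                    code += 1
                    rows.append(
                        {
                            "specimen_id": f"REC{code:06d}",
                            "species": None,
                            "numeric_code": code,
                            "inversion_id": inv,
                            "cyt": float(cyt),
                            "oa": float(mol),
                            "gt": float(mol),
                        }
                    )
        if n_assayed is not None:
            for _ in range(int(n_assayed[inv]) - int(table.sum())):
                code += 1
                rows.append(
                    {
                        "specimen_id": f"REC{code:06d}",
                        "species": None,
                        "numeric_code": code,
                        "inversion_id": inv,
                        "cyt": 0.0,
                        "oa": 1.0,
                        "gt": 0.0,
                    }
                )
    return pd.DataFrame(rows)


def parity_table() -> np.ndarray:
    """The published odd/even x discordant/concordant 2x2 margins."""
    odd_disc = PARITY["n_discordant"] - PARITY["n_even_discordant"]
    return np.array(
        [
            [odd_disc, PARITY["n_odd"] - odd_disc],
            [PARITY["n_even_discordant"], PARITY["n_even"] - PARITY["n_even_discordant"]],
        ]
    )
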