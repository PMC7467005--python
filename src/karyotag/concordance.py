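"""Multi-method genotype agreement: classification, tabulation, parity tests.

Each specimen x inversion carries up to three genotype calls: cytogenetic
(polytene chromosome reading, ``cyt``), array (``oa``) and amplicon
sequencing (``gt``).  Complete triples are classified into agreement
categories; per-inversion summary tables report category counts and
percentages, and a 3x3 contingency (cytogenetic class vs joint molecular
class) breaks down the cases where the two molecular methods agree.  A
parity test asks whether cytogenetic-vs-molecular discordances concentrate
in even- or odd-numbered specimens — a signature of observer error in one of
two karyotyping teams that split specimens by numeric code.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENOTYPES = (0, 1, 2)


class ConcordanceError(ValueError):
    pass


class AgreementCategory(Enum):
    """How the three genotype calls for one specimen x inversion relate."""

    ALL_AGREE = "three_way_agree"
    MOL_AGREE_CYT_DIFF = "cyt_vs_molecular"
    CYT_GT_AGREE_OA_DIFF = "cyt_gt_vs_oa"
    CYT_OA_AGREE_GT_DIFF = "cyt_oa_vs_gt"
    ALL_DIFFER = "three_way_differ"
    INCOMPLETE = "incomplete"


#: The five complete-case categories, in summary-table row order.
COMPLETE_CATEGORIES = [
    AgreementCategory.ALL_AGREE,
    AgreementCategory.MOL_AGREE_CYT_DIFF,
    AgreementCategory.CYT_GT_AGREE_OA_DIFF,
    AgreementCategory.CYT_OA_AGREE_GT_DIFF,
    AgreementCategory.ALL_DIFFER,
]


def classify(cyt, oa, gt) -> AgreementCategory:
    """Assign the agreement category for one genotype triple.

    Any missing value makes the triple INCOMPLETE.  Classification is
    symmetric in the two molecular calls up to swapping the two mixed
    categories.
    """
    vals = []
    for v in (cyt, oa, gt):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            vals.append(None)
            continue
        iv = int(v)
        if iv != v or iv not in GENOTYPES:
            raise ConcordanceError(f"genotype value outside {{0,1,2,missing}}: {v!r}")
        vals.append(iv)
    c, o, g = vals
    if None in vals:
        return AgreementCategory.INCOMPLETE
    if c == o == g:
        return AgreementCategory.ALL_AGREE
    if o == g:
        return AgreementCategory.MOL_AGREE_CYT_DIFF
    if c == g:
        return AgreementCategory.CYT_GT_AGREE_OA_DIFF
    if c == o:
        return AgreementCategory.CYT_OA_AGREE_GT_DIFF
    return AgreementCategory.ALL_DIFFER


def classify_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Add a ``category`` column to a long-format triplicate-calls frame.

    Expected columns: ``specimen_id, species, numeric_code, inversion_id,
    cyt, oa, gt`` (genotypes 0/1/2/NaN).
    """
    out = calls.copy()
    out["category"] = [
        classify(r.cyt, r.oa, r.gt) for r in calls.itertuples(index=False)
    ]
    return out


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero, matching hand-tabulated percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-inversion category counts and percentages over complete cases.

    Returns one row per (inversion, category) plus the complete-case total
    ``n_assayed``; INCOMPLETE triples are excluded from the denominator and
    reported in a separate ``n_incomplete`` column.  Percentages are
    100*count/n rounded half-up to 2 decimals (blank when n is 0).
    """
    df = calls if "category" in calls.columns else classify_calls(calls)
    rows = []
    for inv, group in df.groupby("inversion_id", sort=False):
        complete = group[group["category"] != AgreementCategory.INCOMPLETE]
        n = len(complete)
        n_incomplete = len(group) - n
        counts = complete["category"].value_counts()
        for cat in COMPLETE_CATEGORIES:
            count = int(counts.get(cat, 0))
            rows.append(
                {
                    "inversion_id": inv,
                    "category": cat.value,
                    "count": count,
                    "percent": round_half_up(100.0 * count / n) if n else np.nan,
                    "n_assayed": n,
                    "n_incomplete": n_incomplete,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "inversion_id",
            "category",
            "count",
            "percent",
            "n_assayed",
            "n_incomplete",
        ],
    )


def class_contingency(calls: pd.DataFrame) -> dict[str, np.ndarray]:
    """3x3 cytogenetic-class x joint-molecular-class counts per inversion.

    Restricted to complete triples where the two molecular methods agree
    (three-way agreement plus cytogenetic-vs-molecular discordance); the
    column is the shared molecular genotype.  The diagonal sums to the
    three-way-agreement count and the off-diagonal to the
    cytogenetic-vs-molecular discordance count.
    """
    df = calls if "category" in calls.columns else classify_calls(calls)
    keep = df["category"].isin(
        [AgreementCategory.ALL_AGREE, AgreementCategory.MOL_AGREE_CYT_DIFF]
    )
    out: dict[str, np.ndarray] = {}
    for inv, group in df[keep].groupby("inversion_id", sort=False):
        table = np.zeros((3, 3), dtype=int)
        for r in group.itertuples(index=False):
            table[int(r.cyt), int(r.oa)] += 1  # oa == gt within this subset
        out[inv] = table
    return out


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of counts.

    With margins fixed, p is the sum of hypergeometric probabilities of all
    tables whose point probability does not exceed the observed one (ties
    admitted within a 1e-7 relative tolerance).  Invariant under
    transposition; p is in (0, 1].
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ConcordanceError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ConcordanceError("table entries must be non-negative")
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return 1.0  # degenerate margin: only one table is possible
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    observed = pmf[support == a][0]
    p = float(pmf[pmf <= observed * (1 + 1e-7)].sum())
    return min(p, 1.0)


@dataclass
class ParityTest:
    """Odd/even numeric-code x discordant/concordant contingency analysis."""

    table: np.ndarray  # rows: odd, even; cols: discordant, concordant
    chi2: float
    chi2_p: float
    chi2_yates: float
    chi2_yates_p: float
    fisher_p: float
    unit: str
    n_discordant: int
    n_even_discordant: int


def parity_test(
    calls: pd.DataFrame,
    inversions: Sequence[str] | None = None,
    category: AgreementCategory = AgreementCategory.MOL_AGREE_CYT_DIFF,
    unit: str = "observation",
) -> ParityTest:
    """Test whether discordances concentrate in even- or odd-coded specimens.

    Builds a 2x2 table of specimen-code parity against membership in the
    selected agreement category over the selected inversions, then computes
    chi-square (with and without Yates continuity correction) and the
    two-sided Fisher exact p.  ``unit="observation"`` counts each complete
    specimen x inversion record; ``unit="specimen"`` counts a specimen as
    discordant if any of its records falls in the category.
    """
    if unit not in ("observation", "specimen"):
        raise ConcordanceError(f"unknown unit {unit!r}")
    df = calls if "category" in calls.columns else classify_calls(calls)
    if inversions is not None:
        df = df[df["inversion_id"].isin(list(inversions))]
    df = df[df["category"] != AgreementCategory.INCOMPLETE]
    if df.empty:
        raise ConcordanceError("no complete records selected for parity test")
    if df["numeric_code"].isna().any():
        raise ConcordanceError("parity test requires numeric_code for all specimens")

    df = df.assign(
        even=(df["numeric_code"].astype(int) % 2 == 0),
        hit=(df["category"] == category),
    )
    if unit == "specimen":
        df = df.groupby("specimen_id", sort=False).agg(
            even=("even", "first"), hit=("hit", "any")
        )
    table = np.array(
        [
            [int((~df.even & df.hit).sum()), int((~df.even & ~df.hit).sum())],
            [int((df.even & df.hit).sum()), int((df.even & ~df.hit).sum())],
        ]
    )
    n_disc = int(table[:, 0].sum())
    if n_disc == 0:
        warnings.warn("no discordant records; parity table is degenerate")
    chi2, chi2_p = _chi2(table, correction=False)
    chi2_y, chi2_y_p = _chi2(table, correction=True)
    return ParityTest(
        table=table,
        chi2=chi2,
        chi2_p=chi2_p,
        chi2_yates=chi2_y,
        chi2_yates_p=chi2_y_p,
        fisher_p=fisher_exact_2x2(table),
        unit=unit,
        n_discordant=n_disc,
        n_even_discordant=int(table[1, 0]),
    )


def _chi2(table: np.ndarray, correction: bool) -> tuple[float, float]:
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# I/O and rendering

def load_triplicate_calls(path: str | Path) -> pd.DataFrame:
    """Load long-format triplicate calls CSV.

    Columns: ``specimen_id,species,numeric_code,inversion,cyt,oa,gt`` (the
    inversion column may also be named ``inversion_id``); genotypes 0/1/2/NA.
    """
    df = pd.read_csv(path, na_values=["NA"])
    if "inversion" in df.columns and "inversion_id" not in df.columns:
        df = df.rename(columns={"inversion": "inversion_id"})
    required = {"specimen_id", "numeric_code", "inversion_id", "cyt", "oa", "gt"}
    missing = required - set(df.columns)
    if missing:
        raise ConcordanceError(f"{path}: missing columns {sorted(missing)}")
    if "species" not in df.columns:
        df["species"] = None
    for col in ("cyt", "oa", "gt"):
        df[col] = df[col].astype(float)
    return df


def save_triplicate_calls(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.copy()
    if "category" in out.columns:
        out = out.drop(columns="category")
    out = out.rename(columns={"inversion_id": "inversion"})
    for col in ("cyt", "oa", "gt"):
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False, na_rep="NA")


def contingency_to_frame(tables: dict[str, np.ndarray]) -> pd.DataFrame:
    """Flatten per-inversion 3x3 tables for TSV output."""
    rows = []
    for inv, t in tables.items():
        for cyt in GENOTYPES:
            rows.append(
                {
                    "inversion_id": inv,
                    "cyt": cyt,
                    "mol_0": int(t[cyt, 0]),
                    "mol_1": int(t[cyt, 1]),
                    "mol_2": int(t[cyt, 2]),
                }
            )
    return pd.DataFrame(rows)


CATEGORY_COLORS = {
    AgreementCategory.ALL_AGREE: "#2ca02c",  # green: 3-way concordance
    AgreementCategory.MOL_AGREE_CYT_DIFF: "#ffdf00",  # yellow: molecular pair
    AgreementCategory.CYT_GT_AGREE_OA_DIFF: "#7b2d8b",  # purple
    AgreementCategory.CYT_OA_AGREE_GT_DIFF: "#000000",  # black
    AgreementCategory.ALL_DIFFER: "#d62728",  # red
    AgreementCategory.INCOMPLETE: "#bbbbbb",  # gray: missing data
}


def render_heatmap(calls: pd.DataFrame, path: str | Path) -> None:
    """Render a specimen x inversion agreement-category heat map to a file.

    Rows are specimens grouped by species; cells are coloured by agreement
    category.
    """
    df = calls if "category" in calls.columns else classify_calls(calls)
    if df.empty:
        raise ConcordanceError("no calls to render")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    cats = list(CATEGORY_COLORS)
    code = {cat: i for i, cat in enumerate(cats)}
    pivot = (
        df.assign(code=df["category"].map(code))
        .sort_values(["species", "specimen_id"])
        .pivot_table(
            index="specimen_id", columns="inversion_id", values="code",
            aggfunc="first", sort=False,
        )
    )
    grid = pivot.to_numpy(dtype=float)
    grid[np.isnan(grid)] = code[AgreementCategory.INCOMPLETE]
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.6 * pivot.shape[1], 1.5 + 0.05 * pivot.shape[0])
    )
    ax.imshow(
        grid,
        aspect="auto",
        cmap=ListedColormap([CATEGORY_COLORS[c] for c in cats]),
        vmin=-0.5,
        vmax=len(cats) - 0.5,
        interpolation="nearest",
    )
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks([])
    ax.set_ylabel(f"{pivot.shape[0]} specimens")
    ax.legend(
        handles=[Patch(color=CATEGORY_COLORS[c], label=c.value) for c in cats],
        bbox_to_anchor=(1.02, 1),
        loc="upper left",
        fontsize="small",
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
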