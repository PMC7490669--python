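"""Carrier-rate comparison between cohorts with two-sided Fisher's exact tests.

Compares per-population carrier counts for the CBS c.833T>C SNV and the
c.[833T>C;844_845ins68] complex variant between a reference cohort (gnomAD,
chromosome counts converted to carrier counts) and a clinical screening
cohort.  The published per-population counts ship as a packaged fixture
(``data/cbs_cohort_counts.tsv``); cells whose printed rate does not equal
100*k/n from the printed counts carry a note in the fixture and are excluded
from exact-reproduction checks.

The two-sided p-value is the standard convention: the sum of hypergeometric
probabilities, over all tables with the observed margins, that do not exceed
the probability of the observed table.  A table with a zero margin carries no
contrast and is defined to have p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

__all__ = [
    "ContingencyTable",
    "CohortRow",
    "carrier_rate",
    "fisher_exact_two_sided",
    "load_cohort_counts",
    "compare_cohorts",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (carriers, non-carriers) x (cohort A, cohort B)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @classmethod
    def from_counts(cls, k_a: int, n_a: int, k_b: int, n_b: int) -> "ContingencyTable":
        if k_a > n_a or k_b > n_b:
            raise ValueError("positives exceed totals")
        return cls(k_a, n_a - k_a, k_b, n_b - k_b)

    @property
    def has_zero_margin(self) -> bool:
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


def carrier_rate(k: int, n: int) -> float:
    """Carrier rate 100*k/n as a percentage, rounded half-up to 2 decimals."""
    if n <= 0:
        raise ValueError("cohort total must be positive")
    if not 0 <= k <= n:
        raise ValueError("carrier count must lie in [0, total]")
    rate = Decimal(100 * k) / Decimal(n)
    return float(rate.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table."""
    if t.has_zero_margin:
        return 1.0
    p = _scipy_fisher([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
    return float(min(1.0, max(0.0, p)))


@dataclass(frozen=True)
class CohortRow:
    """One population x variant comparison."""

    population: str
    variant: str
    ref_total: int
    ref_positive: int
    study_total: int
    study_positive: int
    alpha: float = ALPHA

    @property
    def ref_rate(self) -> float:
        return carrier_rate(self.ref_positive, self.ref_total)

    @property
    def study_rate(self) -> float:
        return carrier_rate(self.study_positive, self.study_total)

    @property
    def table(self) -> ContingencyTable:
        return ContingencyTable.from_counts(
            self.ref_positive, self.ref_total, self.study_positive, self.study_total
        )

    @property
    def p_value(self) -> float:
        return fisher_exact_two_sided(self.table)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def load_cohort_counts() -> pd.DataFrame:
    """The packaged per-population carrier-count fixture."""
    with resources.files("scaffoldcall.data").joinpath("cbs_cohort_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"printed_p": str, "note": str})
    df["note"] = df["note"].fillna("")
    df["printed_p"] = df["printed_p"].fillna("")
    return df


def compare_cohorts(
    counts: pd.DataFrame | None = None, alpha: float = ALPHA
) -> pd.DataFrame:
    """Recompute rates, p-values and significance flags for every
    population x variant row.  Rows with missing counts are skipped with a
    warning column note."""
    if counts is None:
        counts = load_cohort_counts()
    rows = []
    for _, rec in counts.iterrows():
        needed = ["ref_total", "ref_positive", "study_total", "study_positive"]
        if rec[needed].isna().any():
            import warnings

            warnings.warn(
                f"skipping row {rec.get('population')}/{rec.get('variant')}: "
                "missing counts",
                stacklevel=2,
            )
            continue
        row = CohortRow(
            population=str(rec["population"]),
            variant=str(rec["variant"]),
            ref_total=int(rec["ref_total"]),
            ref_positive=int(rec["ref_positive"]),
            study_total=int(rec["study_total"]),
            study_positive=int(rec["study_positive"]),
            alpha=alpha,
        )
        rows.append(
            {
                "population": row.population,
                "variant": row.variant,
                "ref_total": row.ref_total,
                "ref_positive": row.ref_positive,
                "study_total": row.study_total,
                "study_positive": row.study_positive,
                "ref_rate": row.ref_rate,
                "study_rate": row.study_rate,
                "p_value": row.p_value,
                "significant": row.significant,
            }
        )
    return pd.DataFrame(rows)
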