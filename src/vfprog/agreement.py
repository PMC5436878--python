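"""Paired-proportion and agreement statistics for SAP vs FDT outcomes.

Both instruments classify each eye as developing a defect or not, so
agreement reduces to a 2x2 cross-classification.  Cohen's kappa measures
chance-corrected agreement and the exact (binomial) McNemar test compares
the two marginal detection proportions using only the discordant cells.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["AgreementTable", "KappaResult", "cohen_kappa", "mcnemar_exact",
           "interpret_kappa"]

#: Landis-Koch interpretation bands; kappa in (0, 0.01) maps to "slight"
#: (the conventional band list starts at 0.01, leaving that sliver
#: unlabeled; it is folded into the adjacent band).
_KAPPA_BANDS = [
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
]


@dataclass(frozen=True)
class AgreementTable:
    """Eye counts: both detected, SAP only, FDT only, neither."""

    n_both: int
    n_sap_only: int
    n_fdt_only: int
    n_neither: int

    def __post_init__(self) -> None:
        if min(self.n_both, self.n_sap_only, self.n_fdt_only, self.n_neither) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_both + self.n_sap_only + self.n_fdt_only + self.n_neither

    @classmethod
    def from_marginals(cls, n_both: int, n_sap_total: int, n_fdt_total: int,
                       n_eyes: int) -> "AgreementTable":
        """Reconstruct the 2x2 table from per-type event totals."""
        b = n_sap_total - n_both
        c = n_fdt_total - n_both
        return cls(n_both, b, c, n_eyes - n_both - b - c)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    interpretation: str


def interpret_kappa(kappa: float) -> str:
    if kappa < 0:
        return "poor"
    for upper, label in _KAPPA_BANDS[1:]:
        if kappa <= upper:
            return label
    return "almost perfect"


def cohen_kappa(table: AgreementTable, conf_level: float = 0.95) -> KappaResult:
    """Cohen's kappa with a large-sample confidence interval.

    kappa = (po - pe) / (1 - pe) with po the observed agreement proportion
    and pe the chance agreement from the marginal products.  The CI uses
    the non-null asymptotic variance of Fleiss, Cohen & Everitt (1969):

        N (1-pe)^2 var = sum_i p_ii [1 - (p_i. + p.i)(1-k)]^2
                         + (1-k)^2 sum_{i!=j} p_ij (p_.i + p_j.)^2
                         - [k - pe (1-k)]^2
    """
    n = table.total
    if n == 0:
        raise ValueError("empty agreement table")
    a, b, c, d = (table.n_both, table.n_sap_only, table.n_fdt_only,
                  table.n_neither)
    p = [[a / n, b / n], [c / n, d / n]]
    row = [p[0][0] + p[0][1], p[1][0] + p[1][1]]  # SAP marginals
    col = [p[0][0] + p[1][0], p[0][1] + p[1][1]]  # FDT marginals
    po = p[0][0] + p[1][1]
    pe = row[0] * col[0] + row[1] * col[1]
    if pe >= 1.0:
        raise ZeroDivisionError("degenerate marginals: chance agreement is 1")
    kappa = (po - pe) / (1 - pe)
    term1 = sum(p[i][i] * (1 - (row[i] + col[i]) * (1 - kappa)) ** 2
                for i in (0, 1))
    term2 = (1 - kappa) ** 2 * sum(
        p[i][j] * (col[i] + row[j]) ** 2
        for i in (0, 1) for j in (0, 1) if i != j
    )
    term3 = (kappa - pe * (1 - kappa)) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 2)
    se = max(var, 0.0) ** 0.5
    z = stats.norm.ppf(0.5 + conf_level / 2)
    return KappaResult(
        kappa=kappa,
        ci_low=max(kappa - z * se, -1.0),
        ci_high=min(kappa + z * se, 1.0),
        interpretation=interpret_kappa(kappa),
    )


def mcnemar_exact(table: AgreementTable) -> float:
    """Exact two-sided McNemar p-value.

    p = 2 P(X <= min(b, c)) for X ~ Binomial(b + c, 1/2), capped at 1;
    b, c are the discordant cells.  Equal discordant counts give p = 1.
    """
    b, c = table.n_sap_only, table.n_fdt_only
    n = b + c
    if n == 0:
        return 1.0
    p = 2.0 * stats.binom.cdf(min(b, c), n, 0.5)
    return min(p, 1.0)
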