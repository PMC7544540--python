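"""Instrumental-variable selection and strength diagnostics.

Selection proceeds in three stages — genome-wide significance filter,
outcome-availability filter, and greedy LD pruning — and keeps a full count
of what each stage removed. Pruning resolves every pair with r2 strictly
above the threshold by discarding the member with the larger exposure
p-value, processing pairs in descending r2 so the result is invariant to
the order of the input table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InstrumentSelectionError
from .sumstats_io import LdTable, SnpAssociation, SummaryStatsTable

GENOME_WIDE_SIGNIFICANCE = 5e-8
DEFAULT_R2_THRESHOLD = 0.1


@dataclass
class InstrumentSet:
    """The retained instruments plus the per-stage selection accounting.

    ``selection_log`` keys: ``input`` (significant SNPs entering selection),
    ``unavailable`` (absent from the outcome), ``pruned`` (removed by LD),
    ``retained``; plus ``supplied`` and ``not_significant`` for the raw table.
    """

    snps: dict[str, SnpAssociation]
    selection_log: dict[str, int]
    p_threshold: float
    r2_threshold: float

    def __post_init__(self) -> None:
        lg = self.selection_log
        assert lg["retained"] == lg["input"] - lg["unavailable"] - lg["pruned"]

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def rsids(self) -> list[str]:
        return list(self.snps)


@dataclass
class InstrumentStrength:
    """Variance explained and the joint F statistic of the instrument set."""

    r_squared: float
    f_statistic: float
    n_exposure: int
    k: int


def select_instruments(
    exposure: SummaryStatsTable,
    outcome_rsids: set[str],
    ld: LdTable | None = None,
    p_threshold: float = GENOME_WIDE_SIGNIFICANCE,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> InstrumentSet:
    """Select the instrument set for one exposure/outcome pair.

    Keeps exposure SNPs with ``pvalue < p_threshold``; drops those absent
    from ``outcome_rsids``; then prunes LD pairs with ``r2 > r2_threshold``
    (strict), removing within each pair the SNP with the larger p-value
    (ties broken toward the lexicographically larger rsid). Raises
    :class:`InstrumentSelectionError` if nothing survives.
    """
    if not (0 < p_threshold < 1) or not (0 < r2_threshold < 1):
        raise DomainError("p_threshold and r2_threshold must lie in (0, 1)")

    supplied = len(exposure)
    significant = {
        rsid: rec for rsid, rec in exposure.records.items() if rec.pvalue < p_threshold
    }
    n_input = len(significant)

    available = {rsid: rec for rsid, rec in significant.items() if rsid in outcome_rsids}
    n_unavailable = n_input - len(available)

    pruned: set[str] = set()
    if ld is not None:
        for a, b, _r2 in ld.pairs_above(r2_threshold):
            if a not in available or b not in available:
                continue
            if a in pruned or b in pruned:
                continue
            pa, pb = available[a].pvalue, available[b].pvalue
            if pa > pb:
                loser = a
            elif pb > pa:
                loser = b
            else:
                loser = max(a, b)
            pruned.add(loser)

    retained = {
        rsid: rec for rsid, rec in sorted(available.items()) if rsid not in pruned
    }
    log = {
        "supplied": supplied,
        "not_significant": supplied - n_input,
        "input": n_input,
        "unavailable": n_unavailable,
        "pruned": len(pruned),
        "retained": len(retained),
    }
    if not retained:
        raise InstrumentSelectionError(
            f"no instruments retained for {exposure.trait_name!r} "
            f"(selection log: {log})"
        )
    return InstrumentSet(
        snps=retained, selection_log=log, p_threshold=p_threshold, r2_threshold=r2_threshold
    )


def per_snp_r2_from_z(z: float, n: int) -> float:
    """Variance explained by one SNP from its z-score and the GWAS sample size."""
    return z * z / (z * z + n - 2)


def per_snp_r2_from_eaf(beta: float, eaf: float) -> float:
    """Variance explained as 2*EAF*(1-EAF)*beta^2 (beta on the SD scale)."""
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def instrument_strength(
    instruments: InstrumentSet,
    n_exposure: int,
    method: str = "z",
) -> InstrumentStrength:
    """Total variance explained and the joint instrument F statistic.

    ``method='z'`` (default) sums per-SNP z-based R2 terms, which needs no
    allele frequencies; ``method='eaf'`` uses 2*EAF*(1-EAF)*beta^2 and
    requires eaf on every record. F = (R2/k) / ((1-R2)/(N-k-1)).
    """
    k = len(instruments)
    if n_exposure <= k + 1:
        raise DomainError(f"n_exposure ({n_exposure}) must exceed k+1 ({k + 1})")
    if method == "z":
        r2 = float(
            np.sum([per_snp_r2_from_z(rec.zscore, n_exposure) for rec in instruments.snps.values()])
        )
    elif method == "eaf":
        if any(rec.eaf is None for rec in instruments.snps.values()):
            raise DomainError("method='eaf' requires eaf on every instrument record")
        r2 = float(
            np.sum([per_snp_r2_from_eaf(rec.beta, rec.eaf) for rec in instruments.snps.values()])
        )
    else:
        raise DomainError(f"unknown method {method!r}; use 'z' or 'eaf'")
    r2 = min(r2, 1.0)
    f_stat = (r2 / k) / ((1.0 - r2) / (n_exposure - k - 1))
    return InstrumentStrength(r_squared=r2, f_statistic=f_stat, n_exposure=n_exposure, k=k)


def f_statistic(r_squared: float, k: int, n_exposure: int) -> float:
    """Joint F from aggregate R2 alone; convenience for published inputs."""
    if not (0 <= r_squared < 1):
        raise DomainError("r_squared must lie in [0, 1)")
    if n_exposure <= k + 1:
        raise DomainError("n_exposure must exceed k+1")
    return (r_squared / k) / ((1.0 - r_squared) / (n_exposure - k - 1))
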