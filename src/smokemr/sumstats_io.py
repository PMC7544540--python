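"""Reading, validating and writing GWAS summary-statistics and LD tables.

All on-disk formats are tab-separated UTF-8 text with a header row. Column
names are mapped through a configurable :data:`DEFAULT_COLUMN_MAP`, so tables
exported from differently formatted consortium pipelines load without
editing. Every downstream module consumes the in-memory containers defined
here: :class:`SnpAssociation`, :class:`SummaryStatsTable`, :class:`LdTable`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: default header names; override any entry via the ``column_map`` argument
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}

_MANDATORY = ("rsid", "effect_allele", "other_allele", "beta", "se", "pvalue")


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association record with a single trait.

    ``beta`` is signed per copy of ``effect_allele``: SD units of smoking
    initiation prevalence on the exposure side, log-odds on a binary outcome
    side. ``eaf`` (effect-allele frequency) and ``n`` may be missing, as they
    often are in consortium exports.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise DataError(
                f"{self.rsid}: alleles must be single bases A/C/G/T "
                f"(got {ea!r}/{oa!r}; indels are not supported)"
            )
        if ea == oa:
            raise DataError(f"{self.rsid}: effect and other allele are identical ({ea})")
        if not self.se > 0:
            raise DataError(f"{self.rsid}: se must be > 0 (got {self.se})")
        if not (0 < self.pvalue <= 1):
            raise DataError(f"{self.rsid}: pvalue must lie in (0, 1] (got {self.pvalue})")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise DataError(f"{self.rsid}: eaf must lie in [0, 1] (got {self.eaf})")
        if self.n is not None and self.n <= 0:
            raise DataError(f"{self.rsid}: n must be a positive integer (got {self.n})")
        self._check_p_consistency()

    def _check_p_consistency(self) -> None:
        # Warn (never fail) when the implied z from beta/se disagrees with
        # the implied z from the p-value by more than 2-fold; rounding in
        # published tables makes small discrepancies routine.
        z_ratio = abs(self.beta / self.se)
        z_p = stats.norm.isf(self.pvalue / 2.0)
        if z_p <= 0 or not math.isfinite(z_p):
            return
        if z_ratio > 0 and not (0.5 <= z_ratio / z_p <= 2.0):
            warnings.warn(
                f"{self.rsid}: |beta/se| = {z_ratio:.3g} implies a z inconsistent "
                f"with pvalue {self.pvalue:.3g} (implied z {z_p:.3g})",
                stacklevel=3,
            )

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def palindromic(self) -> bool:
        """A/T or C/G pairs: strand cannot be inferred from alleles alone."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})

    def flipped(self) -> "SnpAssociation":
        """The same association expressed with the alleles swapped."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class SummaryStatsTable:
    """A full summary-statistics table for one trait, keyed by rsid."""

    trait_name: str
    trait_type: str = "continuous"  # {"binary", "continuous"}
    scale_note: str = ""
    records: dict[str, SnpAssociation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'continuous', got {self.trait_type!r}"
            )
        if not self.records:
            raise DataError(f"summary-statistics table for {self.trait_name!r} is empty")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def __getitem__(self, rsid: str) -> SnpAssociation:
        return self.records[rsid]

    @property
    def rsids(self) -> set[str]:
        return set(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": r.rsid,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": np.nan if r.n is None else r.n,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows)


@dataclass
class LdTable:
    """Pairwise LD lookup; keys are order-insensitive, absent pairs are r2=0."""

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if a == b:
            raise DataError(f"LD table contains a self-pair for {a}")
        if not (0 <= r2 <= 1):
            raise DataError(f"r2 for ({a}, {b}) must lie in [0, 1], got {r2}")
        self.pairs[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        return self.pairs.get(self._key(a, b), 0.0)

    def pairs_above(self, threshold: float) -> list[tuple[str, str, float]]:
        """All stored pairs with r2 strictly greater than ``threshold``."""
        return sorted(
            ((a, b, v) for (a, b), v in self.pairs.items() if v > threshold),
            key=lambda t: (-t[2], t[0], t[1]),
        )


def _parse_optional(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "nan", "."):
        return None
    return float(value)


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "trait",
    trait_type: str = "continuous",
    scale_note: str = "",
) -> SummaryStatsTable:
    """Read a TSV of per-SNP associations into a validated table.

    Rows missing beta or se are dropped (counted in the module log); alleles
    are uppercased. A missing mandatory column raises
    :class:`ConfigurationError` naming it; duplicated rsids raise
    :class:`DataError` listing them.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for field_name in _MANDATORY:
        if cmap[field_name] not in df.columns:
            raise ConfigurationError(
                f"{path}: mandatory column {cmap[field_name]!r} (for {field_name}) not found; "
                f"available columns: {list(df.columns)}"
            )

    records: dict[str, SnpAssociation] = {}
    duplicates: list[str] = []
    n_dropped = 0
    for _, row in df.iterrows():
        beta_raw = _parse_optional(row[cmap["beta"]])
        se_raw = _parse_optional(row[cmap["se"]])
        if beta_raw is None or se_raw is None or se_raw <= 0:
            n_dropped += 1  # unusable association: no beta, or no/degenerate se
            continue
        n_raw = row[cmap["n"]] if cmap["n"] in df.columns else None
        n_val = _parse_optional(n_raw)
        eaf_raw = row[cmap["eaf"]] if cmap["eaf"] in df.columns else None
        rec = SnpAssociation(
            rsid=str(row[cmap["rsid"]]).strip(),
            effect_allele=str(row[cmap["effect_allele"]]).strip().upper(),
            other_allele=str(row[cmap["other_allele"]]).strip().upper(),
            eaf=_parse_optional(eaf_raw),
            beta=beta_raw,
            se=se_raw,
            pvalue=float(row[cmap["pvalue"]]),
            n=None if n_val is None else int(n_val),
        )
        if rec.rsid in records:
            duplicates.append(rec.rsid)
        records[rec.rsid] = rec
    if duplicates:
        raise DataError(f"{path}: duplicate rsids: {sorted(set(duplicates))}")
    if n_dropped:
        log.info("%s: dropped %d row(s) with missing beta or se", path, n_dropped)
    table = SummaryStatsTable(
        trait_name=trait_name, trait_type=trait_type, scale_note=scale_note, records=records
    )
    table.n_dropped_rows = n_dropped  # type: ignore[attr-defined]
    return table


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write a table in the same TSV dialect :func:`read_summary_stats` reads."""
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_ld_table(path) -> LdTable:
    """Read a 3-column (rsid_a, rsid_b, r2) TSV into a symmetric lookup."""
    ld = LdTable()
    df = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
    if df.empty:
        return ld
    for col in ("rsid_a", "rsid_b", "r2"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: LD table must have column {col!r}")
    for _, row in df.iterrows():
        ld.add(str(row["rsid_a"]), str(row["rsid_b"]), float(row["r2"]))
    return ld


def write_ld_table(ld: LdTable, path) -> None:
    rows = [{"rsid_a": a, "rsid_b": b, "r2": v} for (a, b), v in sorted(ld.pairs.items())]
    pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


RESULT_COLUMNS = [
    "outcome",
    "method",
    "n_snps",
    "odds_ratio",
    "or_ci_low",
    "or_ci_high",
    "pvalue",
    "i_squared",
]


def write_results_table(estimates: Iterable, path, heterogeneity: Sequence | None = None) -> None:
    """Write a forest-table style results TSV (method, OR, 95% CI, p, I2, k).

    ORs and CI bounds are rounded to 2 decimals, p-values printed in
    scientific notation. ``heterogeneity`` is an optional parallel sequence of
    :class:`~smokemr.estimators.HeterogeneityStats` (or None entries).
    """
    estimates = list(estimates)
    het = list(heterogeneity) if heterogeneity is not None else [None] * len(estimates)
    if len(het) != len(estimates):
        raise ConfigurationError("heterogeneity sequence must match estimates length")
    rows = []
    for est, h in zip(estimates, het):
        rows.append(
            {
                "outcome": getattr(est, "outcome", "") or "",
                "method": est.method,
                "n_snps": est.n_snps,
                "odds_ratio": f"{est.odds_ratio:.2f}",
                "or_ci_low": f"{est.or_ci_low:.2f}",
                "or_ci_high": f"{est.or_ci_high:.2f}",
                "pvalue": f"{est.pvalue:.2e}",
                "i_squared": "" if h is None else f"{h.i_squared:.1f}",
            }
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
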