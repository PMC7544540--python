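"""Synthetic GWAS summary-statistics generator with known ground truth.

The generator emulates the statistical structure of a two-sample MR study
of smoking initiation: 361 independent instruments whose SD-scale exposure
effects jointly explain ~2.3% of phenotypic variance in an exposure GWAS of
1,232,091 individuals, and per-SNP outcome effects on the log-odds scale
from an outcome GWAS of 367,643 individuals. Per instrument j,

    beta_hat_Xj = beta_Xj + N(0, sigma_Xj),    sigma_Xj = 1/sqrt(N_exp)
    beta_hat_Yj = theta * beta_Xj + alpha_j + sum_c gamma_c * g_cj + N(0, sigma_Yj)

where alpha_j are per-SNP direct (pleiotropic) effects drawn per the chosen
mode, and g_cj are per-confounder SNP effects correlated with beta_Xj at the
configured genetic correlation. The generator can additionally inject LD
pairs, SNPs missing from the outcome, and allele-scrambled outcome records,
with a complete truth manifest, so selection and harmonization are testable
end to end. All randomness flows from one seeded generator per bundle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .instruments import GENOME_WIDE_SIGNIFICANCE
from .sumstats_io import (
    LdTable,
    SnpAssociation,
    SummaryStatsTable,
    write_ld_table,
    write_summary_stats,
)

#: genetic correlations of smoking initiation with its main genetically
#: correlated confounders; outcome path coefficients default to zero so the
#: baseline bundle satisfies the exclusion restriction.
DEFAULT_CONFOUNDER_RG = {"alcohol": 0.36, "bmi": 0.12, "education": -0.40}

_NON_PALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class ConfounderPath:
    """One confounder's genetic correlation with the exposure and its causal
    effect on the outcome (log-odds per SD); outcome_effect 0 means the
    confounder exists genetically but opens no pleiotropic path."""

    r_g: float
    outcome_effect: float = 0.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle. Defaults mirror the real
    study: 361 instruments, total R2 0.023, exposure N 1,232,091, outcome N
    367,643."""

    seed: int
    n_snps: int = 361
    n_exposure: int = 1_232_091
    n_outcome: int = 367_643
    target_r2: float = 0.023
    theta: float | Mapping[str, float] = 0.0
    outcome_names: tuple[str, ...] = ("outcome",)
    outcome_case_fraction: float = 0.25
    pleiotropy: str = "none"  # {"none", "balanced", "directional"}
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 0.3
    inside_violation: bool = False
    n_ld_pairs: int = 0
    n_missing: int = 0
    allele_scramble_rate: float = 0.0
    palindromic_fraction: float = 0.0
    confounder_effects: Mapping[str, ConfounderPath] = field(default_factory=dict)
    equal_beta: bool = False
    significance_floor: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.target_r2 < 1):
            raise ConfigurationError(f"target_r2 must lie in (0, 1), got {self.target_r2}")
        if self.n_snps < 3:
            raise ConfigurationError(f"n_snps must be >= 3, got {self.n_snps}")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if 2 * self.n_ld_pairs + self.n_missing > self.n_snps:
            raise ConfigurationError("n_ld_pairs/n_missing exceed the SNP count")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")

    def thetas(self) -> dict[str, float]:
        if isinstance(self.theta, Mapping):
            return dict(self.theta)
        return {name: float(self.theta) for name in self.outcome_names}


@dataclass
class SimulationTruth:
    """Ground truth and injection manifest for one bundle."""

    theta_true: dict[str, float]
    beta_x_true: dict[str, float]
    alpha: dict[str, float]
    valid_fraction: float
    ld_pairs: list[tuple[str, str, float]]
    missing: list[str]
    scrambled: dict[str, dict[str, str]]  # outcome -> rsid -> action
    confounder_beta_true: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class SimulationBundle:
    exposure: SummaryStatsTable
    outcomes: dict[str, SummaryStatsTable]
    confounders: dict[str, SummaryStatsTable]
    ld: LdTable
    truth: SimulationTruth

    def write(self, out_dir: str | Path) -> None:
        """Write all tables in the TSV dialects the IO module reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_summary_stats(self.exposure, out / "exposure.tsv")
        for name, tbl in self.outcomes.items():
            write_summary_stats(tbl, out / f"outcome_{name}.tsv")
        for name, tbl in self.confounders.items():
            write_summary_stats(tbl, out / f"confounder_{name}.tsv")
        write_ld_table(self.ld, out / "ld.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(asdict(self.truth), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def _draw_alpha(
    cfg: SimulationConfig,
    z_true: np.ndarray,
    sign: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-SNP direct effects, expressed relative to the exposure-increasing
    allele (the orientation under which the Egger intercept estimates their
    mean), then mapped back to each SNP's reported allele."""
    n = cfg.n_snps
    alpha = np.zeros(n)
    if cfg.pleiotropy == "none":
        return alpha
    n_invalid = int(round(cfg.pleiotropy_frac * n))
    invalid = rng.choice(n, size=n_invalid, replace=False)
    draws = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_invalid)
    if cfg.pleiotropy == "balanced":
        draws = draws - cfg.pleiotropy_mean  # force mean-zero direct effects
    if cfg.inside_violation:
        # tie direct effects to instrument strength, violating InSIDE
        strength = np.abs(z_true[invalid]) / np.mean(np.abs(z_true))
        draws = draws * strength
    alpha[invalid] = draws * sign[invalid]
    return alpha


def simulate_effects(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Draw all true and observed effect arrays for one bundle (no tables).

    Returns a dict of arrays; :func:`simulate_bundle` wraps them into the
    on-disk container types. Exposed separately so replicate studies can
    skip table construction. LD-pair injection happens here, before outcome
    generation, so a correlated duplicate's outcome beta is consistent with
    its (modified) exposure beta.
    """
    n = cfg.n_snps
    # allocate per-SNP variance explained; exponential tails let a few
    # strong instruments dominate, as in real GWAS
    if cfg.equal_beta:
        shares = np.full(n, 1.0 / n)
    else:
        e = rng.exponential(1.0, size=n)
        shares = e / e.sum()
    r2_j = cfg.target_r2 * shares
    z_true = np.sqrt(r2_j * (cfg.n_exposure - 2) / (1.0 - r2_j))
    if cfg.significance_floor:
        z_min = stats.norm.isf(GENOME_WIDE_SIGNIFICANCE / 2.0)
        z_true = np.maximum(z_true, z_min + 1.5)
    sign = rng.choice([-1.0, 1.0], size=n)
    se_x = np.full(n, 1.0 / math.sqrt(cfg.n_exposure))
    beta_x = sign * z_true * se_x

    # inject correlated duplicates: disjoint pairs (a, b) where b's true
    # effect becomes a noisy copy of a's at correlation r = sqrt(r2)
    ld_pairs_idx: list[tuple[int, int, float]] = []
    if cfg.n_ld_pairs:
        reserved = rng.permutation(n)
        for p in range(cfg.n_ld_pairs):
            ia, ib = int(reserved[2 * p]), int(reserved[2 * p + 1])
            r2 = float(rng.uniform(0.15, 0.95))
            r = math.sqrt(r2)
            beta_x[ib] = r * beta_x[ia] + math.sqrt(1 - r2) * rng.normal(
                0.0, abs(beta_x[ia])
            )
            if cfg.significance_floor:
                floor = (stats.norm.isf(GENOME_WIDE_SIGNIFICANCE / 2.0) + 1.5) * se_x[ib]
                if abs(beta_x[ib]) < floor:
                    beta_x[ib] = math.copysign(floor, beta_x[ib])
            ld_pairs_idx.append((ia, ib, r2))

    beta_x_hat = beta_x + rng.normal(0.0, se_x)
    if cfg.significance_floor:
        # the source instruments are genome-wide significant by construction;
        # redraw sampling noise for any SNP whose observed p would fail
        for _ in range(100):
            p_obs = _pvalue(beta_x_hat, se_x)
            bad = p_obs >= GENOME_WIDE_SIGNIFICANCE
            if not bad.any():
                break
            beta_x_hat[bad] = beta_x[bad] + rng.normal(0.0, se_x[bad])

    alpha = _draw_alpha(cfg, z_true, sign, rng)

    cf = cfg.outcome_case_fraction
    se_y_base = 1.0 / math.sqrt(cfg.n_outcome * cf * (1.0 - cf))

    conf_true: dict[str, np.ndarray] = {}
    conf_hat: dict[str, np.ndarray] = {}
    sd_bx = float(np.std(beta_x)) or se_x[0]
    for name, path in sorted(cfg.confounder_effects.items()):
        g = path.r_g * beta_x + math.sqrt(max(0.0, 1 - path.r_g**2)) * rng.normal(
            0.0, sd_bx, size=n
        )
        conf_true[name] = g
        conf_hat[name] = g + rng.normal(0.0, se_x)

    outcomes: dict[str, dict[str, np.ndarray]] = {}
    for name, theta in sorted(cfg.thetas().items()):
        se_y = se_y_base * rng.uniform(0.9, 1.1, size=n)
        mean = theta * beta_x + alpha
        for cname, path in sorted(cfg.confounder_effects.items()):
            mean = mean + path.outcome_effect * conf_true[cname]
        beta_y_hat = mean + rng.normal(0.0, se_y)
        outcomes[name] = {"beta": beta_y_hat, "se": se_y, "pvalue": _pvalue(beta_y_hat, se_y)}

    return {
        "beta_x_true": beta_x,
        "beta_x_hat": beta_x_hat,
        "se_x": se_x,
        "pvalue_x": _pvalue(beta_x_hat, se_x),
        "alpha": alpha,
        "outcomes": outcomes,
        "confounder_true": conf_true,
        "confounder_hat": conf_hat,
        "se_y_base": se_y_base,
        "ld_pairs_idx": ld_pairs_idx,
    }


def _records_from_arrays(rsids, alleles, eaf, beta, se, pvalue, n) -> dict[str, SnpAssociation]:
    recs = {}
    for i, rsid in enumerate(rsids):
        recs[rsid] = SnpAssociation(
            rsid=rsid,
            effect_allele=alleles[i][0],
            other_allele=alleles[i][1],
            eaf=float(eaf[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            pvalue=float(pvalue[i]),
            n=n,
        )
    return recs


def simulate_bundle(cfg: SimulationConfig) -> SimulationBundle:
    """Generate one complete bundle of exposure/outcome/confounder tables,
    an LD table, and the truth manifest. Reproducible given the seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    rsids = [f"rs{100001 + i}" for i in range(n)]

    n_pal = int(round(cfg.palindromic_fraction * n))
    pal_idx = set(rng.choice(n, size=n_pal, replace=False).tolist()) if n_pal else set()
    alleles = []
    for i in range(n):
        pool = _PALINDROMIC if i in pal_idx else _NON_PALINDROMIC
        alleles.append(pool[rng.integers(len(pool))])
    eaf = rng.uniform(0.05, 0.95, size=n)

    eff = simulate_effects(cfg, rng)

    ld = LdTable()
    ld_pairs: list[tuple[str, str, float]] = []
    pair_members: set[int] = set()
    for ia, ib, r2 in eff["ld_pairs_idx"]:
        pair_members.update((ia, ib))
        a, b = rsids[ia], rsids[ib]
        ld.add(a, b, r2)
        ld_pairs.append((a, b, r2))

    # SNPs absent from every outcome table, drawn outside the LD pairs
    free = [i for i in range(n) if i not in pair_members]
    missing_idx = set(
        int(i) for i in rng.choice(free, size=cfg.n_missing, replace=False)
    ) if cfg.n_missing else set()
    missing = sorted(rsids[i] for i in missing_idx)

    exposure = SummaryStatsTable(
        trait_name="smoking_initiation",
        trait_type="binary",
        scale_note="SD of prevalence",
        records=_records_from_arrays(
            rsids, alleles, eaf, eff["beta_x_hat"], eff["se_x"], eff["pvalue_x"], cfg.n_exposure
        ),
    )

    outcomes: dict[str, SummaryStatsTable] = {}
    scrambled: dict[str, dict[str, str]] = {}
    for name in sorted(eff["outcomes"]):
        o = eff["outcomes"][name]
        recs: dict[str, SnpAssociation] = {}
        actions: dict[str, str] = {}
        for i, rsid in enumerate(rsids):
            if i in missing_idx:
                continue
            ea, oa = alleles[i]
            beta, snp_eaf = float(o["beta"][i]), float(eaf[i])
            if cfg.allele_scramble_rate and rng.uniform() < cfg.allele_scramble_rate:
                if i not in pal_idx and rng.uniform() < 0.5:
                    # report the complementary strand; effect unchanged
                    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
                    ea, oa = comp[ea], comp[oa]
                    actions[rsid] = "strand"
                else:
                    # swap effect/other allele; sign and frequency flip
                    ea, oa = oa, ea
                    beta, snp_eaf = -beta, 1.0 - snp_eaf
                    actions[rsid] = "swap"
            recs[rsid] = SnpAssociation(
                rsid=rsid, effect_allele=ea, other_allele=oa, eaf=snp_eaf,
                beta=beta, se=float(o["se"][i]), pvalue=float(o["pvalue"][i]),
                n=cfg.n_outcome,
            )
        outcomes[name] = SummaryStatsTable(
            trait_name=name, trait_type="binary", scale_note="log-odds", records=recs
        )
        scrambled[name] = actions

    confounders = {
        name: SummaryStatsTable(
            trait_name=name,
            trait_type="continuous",
            scale_note="SD units",
            records=_records_from_arrays(
                rsids, alleles, eaf, eff["confounder_hat"][name], eff["se_x"],
                _pvalue(eff["confounder_hat"][name], eff["se_x"]), cfg.n_exposure,
            ),
        )
        for name in sorted(eff["confounder_hat"])
    }

    truth = SimulationTruth(
        theta_true=cfg.thetas(),
        beta_x_true={rsid: float(b) for rsid, b in zip(rsids, eff["beta_x_true"])},
        alpha={rsid: float(a) for rsid, a in zip(rsids, eff["alpha"])},
        valid_fraction=float(np.mean(eff["alpha"] == 0.0)),
        ld_pairs=ld_pairs,
        missing=missing,
        scrambled=scrambled,
        confounder_beta_true={
            name: {rsid: float(b) for rsid, b in zip(rsids, arr)}
            for name, arr in eff["confounder_true"].items()
        },
    )
    return SimulationBundle(
        exposure=exposure, outcomes=outcomes, confounders=confounders, ld=ld, truth=truth
    )


def child_seed(seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    return int(np.random.SeedSequence([seed, replicate]).generate_state(1)[0] % (2**31 - 1))


def make_study_shaped_fixture(seed: int, theta: float = math.log(1.81)) -> SimulationBundle:
    """A bundle with the published selection accounting: 378 genome-wide
    significant exposure SNPs, exactly 1 absent from the outcome, exactly 16
    disjoint LD pairs with r2 > 0.1 — so selection must retain exactly 361.

    The default causal effect mirrors the peripheral-arterial-disease odds
    ratio of 1.81 per SD of smoking-initiation prevalence.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_snps=378,
        n_ld_pairs=16,
        n_missing=1,
        theta=theta,
        outcome_names=("peripheral_arterial_disease",),
        outcome_case_fraction=0.02,
        significance_floor=True,
    )
    return simulate_bundle(cfg)
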