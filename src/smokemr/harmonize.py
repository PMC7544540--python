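"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs both betas expressed per copy of the *same* effect
allele. For each instrument the outcome record is compared with the
exposure record: identical orientation is kept as is; swapped alleles flip
the outcome beta's sign; complementary alleles are interpreted as a strand
flip and re-compared. Palindromic SNPs (A/T, C/G) are ambiguous — a strand
flip looks identical to an allele swap — and are resolved by allele
frequency where that is safe, dropped otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import ConfigurationError, HarmonizationError
from .instruments import InstrumentSet
from .sumstats_io import SnpAssociation, SummaryStatsTable

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: palindrome policies: drop only frequency-ambiguous palindromes (default),
#: drop every palindrome, or assume both studies report the forward strand.
PALINDROME_POLICIES = ("drop_ambiguous", "drop_all", "keep_assume_forward")

#: eaf window within which a palindromic SNP cannot be oriented by frequency
DEFAULT_EAF_WINDOW = (0.42, 0.58)

ACTIONS = (
    "kept",
    "outcome_sign_flipped",
    "strand_flipped",
    "dropped_palindromic",
    "dropped_allele_mismatch",
)


@dataclass(frozen=True)
class HarmonizedInstrument:
    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    action: str


@dataclass
class HarmonizedSet:
    """Non-dropped harmonized instruments plus counts of each drop reason."""

    instruments: list[HarmonizedInstrument]
    drop_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.instruments)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        bx = np.array([i.beta_exp for i in self.instruments])
        sx = np.array([i.se_exp for i in self.instruments])
        by = np.array([i.beta_out for i in self.instruments])
        sy = np.array([i.se_out for i in self.instruments])
        return bx, sx, by, sy

    @classmethod
    def from_arrays(cls, beta_exp, se_exp, beta_out, se_out) -> "HarmonizedSet":
        instruments = [
            HarmonizedInstrument(f"rs{i}", float(bx), float(sx), float(by), float(sy), "kept")
            for i, (bx, sx, by, sy) in enumerate(zip(beta_exp, se_exp, beta_out, se_out))
        ]
        return cls(instruments=instruments, drop_log={})


def _complemented(rec: SnpAssociation) -> SnpAssociation:
    from dataclasses import replace

    return replace(
        rec,
        effect_allele=COMPLEMENT[rec.effect_allele],
        other_allele=COMPLEMENT[rec.other_allele],
    )


def _orient_palindrome(
    exp: SnpAssociation,
    out: SnpAssociation,
    policy: str,
    eaf_window: tuple[float, float],
) -> tuple[SnpAssociation | None, str]:
    if policy == "drop_all":
        return None, "dropped_palindromic"
    if policy == "keep_assume_forward":
        if (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele):
            return out, "kept"
        return out.flipped(), "outcome_sign_flipped"
    # drop_ambiguous: orient by frequency agreement when both eafs are
    # decisively away from 0.5, otherwise the strand cannot be recovered.
    lo, hi = eaf_window
    if exp.eaf is None or out.eaf is None:
        return None, "dropped_palindromic"
    if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
        return None, "dropped_palindromic"
    same_side = (exp.eaf > 0.5) == (out.eaf > 0.5)
    if same_side:
        action = (
            "kept"
            if (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele)
            else "strand_flipped"
        )
        return out, action
    return out.flipped(), "outcome_sign_flipped"


def harmonize_record(
    exp: SnpAssociation,
    out: SnpAssociation,
    palindrome_policy: str = "drop_ambiguous",
    eaf_window: tuple[float, float] = DEFAULT_EAF_WINDOW,
) -> HarmonizedInstrument:
    """Harmonize one exposure/outcome record pair to the exposure's alleles."""
    exp_pair = (exp.effect_allele, exp.other_allele)

    if exp.palindromic():
        oriented, action = _orient_palindrome(exp, out, palindrome_policy, eaf_window)
    elif (out.effect_allele, out.other_allele) == exp_pair:
        oriented, action = out, "kept"
    elif (out.other_allele, out.effect_allele) == exp_pair:
        oriented, action = out.flipped(), "outcome_sign_flipped"
    else:
        comp = _complemented(out)
        if (comp.effect_allele, comp.other_allele) == exp_pair:
            oriented, action = comp, "strand_flipped"
        elif (comp.other_allele, comp.effect_allele) == exp_pair:
            # strand flip plus allele swap; the sign flip is what matters
            oriented, action = comp.flipped(), "outcome_sign_flipped"
        else:
            oriented, action = None, "dropped_allele_mismatch"

    if oriented is None:
        return HarmonizedInstrument(exp.rsid, np.nan, np.nan, np.nan, np.nan, action)
    return HarmonizedInstrument(
        rsid=exp.rsid,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=oriented.beta,
        se_out=oriented.se,
        action=action,
    )


def harmonize(
    exposure: InstrumentSet,
    outcome: SummaryStatsTable,
    palindrome_policy: str = "drop_ambiguous",
    eaf_window: tuple[float, float] = DEFAULT_EAF_WINDOW,
) -> HarmonizedSet:
    """Align every instrument's outcome record to the exposure effect allele.

    Returns the non-dropped instruments with a per-reason drop log; raises
    :class:`HarmonizationError` if no instrument survives.
    """
    if palindrome_policy not in PALINDROME_POLICIES:
        raise ConfigurationError(
            f"palindrome_policy must be one of {PALINDROME_POLICIES}, got {palindrome_policy!r}"
        )
    kept: list[HarmonizedInstrument] = []
    drop_log = {"dropped_palindromic": 0, "dropped_allele_mismatch": 0, "missing_in_outcome": 0}
    for rsid, exp_rec in exposure.snps.items():
        if rsid not in outcome:
            drop_log["missing_in_outcome"] += 1
            continue
        inst = harmonize_record(exp_rec, outcome[rsid], palindrome_policy, eaf_window)
        if inst.action.startswith("dropped"):
            drop_log[inst.action] += 1
        else:
            kept.append(inst)
    if not kept:
        raise HarmonizationError(
            f"harmonization against {outcome.trait_name!r} dropped every instrument "
            f"(drop log: {drop_log})"
        )
    return HarmonizedSet(instruments=kept, drop_log=drop_log)
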