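"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR requires the SNP-exposure and SNP-outcome effects to be
expressed for the same effect allele.  Outcome records whose effect
allele equals the exposure's *other* allele are sign-flipped (and their
effect-allele frequency complemented); palindromic variants (A/T, G/C),
whose strand cannot be resolved from the alleles, are resolved through
allele frequencies or dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class PalindromePolicy(str, Enum):
    """How to treat palindromic (strand-ambiguous) variants."""

    DROP_ALL = "drop_all"
    DROP_IF_EAF_MISSING_OR_AMBIGUOUS = "drop_if_eaf_missing_or_ambiguous"


@dataclass
class HarmonizedSet:
    """Aligned per-SNP exposure/outcome effects ready for MR.

    All vectors share one order; ``exclusions`` accounts for every input
    SNP that was not retained, as ``(snp_id, reason)`` pairs.
    """

    snp_ids: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    eaf: np.ndarray
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    flipped: np.ndarray | None = None  #: True where the outcome beta was sign-flipped

    def __post_init__(self) -> None:
        self.bx = np.asarray(self.bx, dtype=float)
        self.sx = np.asarray(self.sx, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        self.eaf = np.asarray(self.eaf, dtype=float)
        n = len(self.snp_ids)
        for v in (self.bx, self.sx, self.by, self.sy, self.eaf):
            if v.shape != (n,):
                raise ValueError("harmonized vectors must share one length")
        if n and (np.any(self.sx <= 0) or np.any(self.sy <= 0)):
            raise ValueError("standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        mask = np.asarray(mask)
        ids = [s for s, m in zip(self.snp_ids, mask) if m]
        return HarmonizedSet(ids, self.bx[mask], self.sx[mask], self.by[mask],
                             self.sy[mask], self.eaf[mask],
                             flipped=None if self.flipped is None else self.flipped[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_ids, "bx": self.bx, "sx": self.sx,
            "by": self.by, "sy": self.sy, "eaf": self.eaf,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HarmonizedSet":
        return cls(list(df["snp_id"].astype(str)), df["bx"].to_numpy(float),
                   df["sx"].to_numpy(float), df["by"].to_numpy(float),
                   df["sy"].to_numpy(float),
                   df["eaf"].to_numpy(float) if "eaf" in df else np.full(len(df), np.nan))


class EmptyOverlapError(ValueError):
    """No SNP is shared between the exposure and outcome tables."""


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff {a1, a2} is {A, T} or {C, G}.

    Multi-base alleles (indels) return False with a logged note: they
    carry strand information and cannot be palindromic in this sense.
    """
    a1, a2 = str(a1).upper(), str(a2).upper()
    if len(a1) != 1 or len(a2) != 1:
        logger.info("multi-base alleles %s/%s treated as non-palindromic", a1, a2)
        return False
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, b) for b in allele.upper())


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_policy: PalindromePolicy | str = PalindromePolicy.DROP_IF_EAF_MISSING_OR_AMBIGUOUS,
    eaf_ambiguity_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome records onto the exposure's effect-allele orientation.

    Parameters
    ----------
    exposure, outcome
        Validated canonical summary-stat tables (see :mod:`mrpipe.io`),
        joined on ``snp_id``.
    palindrome_policy
        ``drop_all`` removes every palindromic SNP; the default retains a
        palindromic SNP only when both EAFs are present, both lie outside
        ``0.5 ± eaf_ambiguity_window``, and the frequencies identify the
        same minor allele (a disagreement implies a strand flip, which is
        then corrected).
    eaf_ambiguity_window
        Half-width w of the ambiguous frequency band [0.5−w, 0.5+w].

    Returns
    -------
    :class:`HarmonizedSet` with every input exposure SNP accounted for in
    either the retained vectors or the exclusion list.
    """
    policy = PalindromePolicy(palindrome_policy)
    out_idx = outcome.set_index(outcome["snp_id"].astype(str))
    if not exposure["snp_id"].astype(str).isin(out_idx.index).any():
        raise EmptyOverlapError(
            f"no overlapping SNPs (exposure has {len(exposure)}, outcome has {len(outcome)})")

    ids: list[str] = []
    bx, sx, by, sy, eaf, flipped = [], [], [], [], [], []
    exclusions: list[tuple[str, str]] = []

    for row in exposure.itertuples(index=False):
        sid = str(row.snp_id)
        if sid not in out_idx.index:
            exclusions.append((sid, "missing_in_outcome"))
            continue
        o = out_idx.loc[sid]
        ea_x, oa_x = str(row.effect_allele), str(row.other_allele)
        ea_y, oa_y = str(o["effect_allele"]), str(o["other_allele"])
        palindromic = is_palindromic(ea_x, oa_x)

        flip: bool | None = None
        if (ea_y, oa_y) == (ea_x, oa_x):
            flip = False
        elif (ea_y, oa_y) == (oa_x, ea_x):
            flip = True
        elif not palindromic:
            # try the complementary strand
            ea_c, oa_c = _complement(ea_y), _complement(oa_y)
            if (ea_c, oa_c) == (ea_x, oa_x):
                flip = False
            elif (ea_c, oa_c) == (oa_x, ea_x):
                flip = True
        if flip is None:
            exclusions.append((sid, "allele_mismatch"))
            continue

        b_y = float(o["beta"])
        e_y = float(o["eaf"]) if pd.notna(o["eaf"]) else np.nan
        if flip:
            b_y = -b_y
            e_y = 1.0 - e_y if np.isfinite(e_y) else np.nan
        e_x = float(row.eaf) if pd.notna(row.eaf) else np.nan

        if palindromic:
            if policy is PalindromePolicy.DROP_ALL:
                exclusions.append((sid, "palindromic"))
                continue
            w = eaf_ambiguity_window
            ambiguous = (
                not np.isfinite(e_x) or not np.isfinite(e_y)
                or abs(e_x - 0.5) <= w or abs(e_y - 0.5) <= w
            )
            if ambiguous:
                exclusions.append((sid, "palindromic"))
                continue
            if (e_x < 0.5) != (e_y < 0.5):
                # frequencies name different minor alleles: the outcome is on
                # the opposite strand, so the nominal alignment was inverted
                b_y, e_y = -b_y, 1.0 - e_y
                flip = not flip

        ids.append(sid)
        bx.append(float(row.beta)); sx.append(float(row.se))
        by.append(b_y); sy.append(float(o["se"]))
        eaf.append(e_x if np.isfinite(e_x) else e_y)
        flipped.append(flip)

    hs = HarmonizedSet(ids, np.array(bx), np.array(sx), np.array(by), np.array(sy),
                       np.array(eaf), exclusions=exclusions,
                       flipped=np.array(flipped, dtype=bool))
    for sid, why in exclusions:
        logger.info("harmonize excluded %s: %s", sid, why)
    return hs
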