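"""Differential-methylation testing and the replicate-design audit.

Because technical replicates of the same pooled DNA carry no biological
differences, a replicate plate supports two constructed audits:

* **consistency pairs** — the same two subjects compared twice, once with
  replicates spread across arrays and once with all replicates on a single
  array; any disagreement between the two significant sets is technical;
* **null designs** — groups with identical subject composition on both
  sides; every significant probe is a false positive by construction.  The
  bundled null design deliberately splits the two sides along chamber
  number, so it is sensitive to positional bias.

Per-probe testing is a pooled-variance two-sample t-test (the linear-model
two-group statistic), with Welch's variant behind a flag; multiplicity is
controlled by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import SampleSheet, ValidationError

DEFAULT_ALPHA = 0.05


class DesignError(ValueError):
    """Raised when an audit design is invalid or cannot be built."""


@dataclass
class AuditDesign:
    """A two-group comparison over named samples."""

    comparison_id: str
    group_a: list
    group_b: list
    audit_kind: str  # consistency_pair | null
    layout_note: str = ""
    pair_id: str | None = None  # links the two arms of a consistency pair

    def __post_init__(self) -> None:
        if self.audit_kind not in ("consistency_pair", "null"):
            raise DesignError(f"unknown audit_kind {self.audit_kind!r}")
        if set(self.group_a) & set(self.group_b):
            raise DesignError(f"{self.comparison_id}: groups overlap")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise DesignError(f"{self.comparison_id}: each group needs >= 2 samples")

    def validate_against(self, sheet: SampleSheet) -> None:
        known = set(sheet.sample_ids)
        missing = [s for s in [*self.group_a, *self.group_b] if s not in known]
        if missing:
            raise DesignError(
                f"{self.comparison_id}: samples absent from sheet: {missing}"
            )
        if self.audit_kind == "null":
            subj = sheet.subject_of()
            if Counter(subj[s] for s in self.group_a) != Counter(
                subj[s] for s in self.group_b
            ):
                raise DesignError(
                    f"{self.comparison_id}: null design requires identical "
                    "subject composition on both sides"
                )


# ---------------------------------------------------------------------------
# per-probe tests and multiplicity control
# ---------------------------------------------------------------------------


def dmp_test(
    matrix: pd.DataFrame,
    group_a: list,
    group_b: list,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sample t-test per probe (pooled variance by default).

    Returns a frame with ``statistic`` (sign: group_a minus group_b), ``p``
    and a ``zero_variance`` flag; zero-pooled-variance probes get NaN p and
    are meant to be excluded from the BH family.
    """
    a = matrix[list(group_a)].to_numpy(float)
    b = matrix[list(group_b)].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each group needs >= 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    stat = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)
    # exact-constancy check (a variance computed in floating point can come
    # out as a denormal for constant inputs)
    zero_var = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0)
    stat[zero_var & (a.mean(axis=1) == b.mean(axis=1))] = 0.0
    p[zero_var] = np.nan
    return pd.DataFrame(
        {"statistic": stat, "p": p, "zero_variance": zero_var}, index=matrix.index
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-preserving)."""
    p = np.asarray(pvalues, float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# audit driver
# ---------------------------------------------------------------------------


@dataclass
class AuditReport:
    """Significant-probe counts per design plus consistency-pair overlaps."""

    per_design: pd.DataFrame
    pairs: pd.DataFrame
    significant_sets: dict  # comparison_id -> frozenset of probe ids
    alpha: float


def run_audit(
    matrix: pd.DataFrame,
    sheet: SampleSheet,
    designs: list,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
) -> AuditReport:
    """Run every design, count BH-significant probes, summarize pairs.

    Null designs report their significant count as ``false_positives``;
    consistency pairs (same ``pair_id``) get overlap counts and Jaccard
    similarity of their significant sets.
    """
    rows = []
    sig_sets: dict = {}
    for design in designs:
        design.validate_against(sheet)
        res = dmp_test(matrix, design.group_a, design.group_b, welch=welch)
        res["p_bh"] = bh_adjust(res["p"].to_numpy())
        sig = res.index[(res["p_bh"] <= alpha).fillna(False)]
        sig_sets[design.comparison_id] = frozenset(sig)
        rows.append(
            {
                "comparison_id": design.comparison_id,
                "audit_kind": design.audit_kind,
                "pair_id": design.pair_id,
                "n_a": len(design.group_a),
                "n_b": len(design.group_b),
                "n_tested": int(res["p"].notna().sum()),
                "n_zero_variance": int(res["zero_variance"].sum()),
                "n_significant": len(sig),
                "false_positives": len(sig) if design.audit_kind == "null" else np.nan,
            }
        )
    per_design = pd.DataFrame(rows)

    pair_rows = []
    pair_groups = per_design.dropna(subset=["pair_id"]).groupby("pair_id")
    for pair_id, grp in pair_groups:
        if len(grp) != 2:
            raise DesignError(f"pair {pair_id!r} must have exactly two designs")
        id1, id2 = grp["comparison_id"]
        s1, s2 = sig_sets[id1], sig_sets[id2]
        union = s1 | s2
        pair_rows.append(
            {
                "pair_id": pair_id,
                "n_sig_1": len(s1),
                "n_sig_2": len(s2),
                "overlap": len(s1 & s2),
                "jaccard": len(s1 & s2) / len(union) if union else np.nan,
            }
        )
    return AuditReport(
        per_design=per_design,
        pairs=pd.DataFrame(pair_rows),
        significant_sets=sig_sets,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# designs over the replicate-plate layout
# ---------------------------------------------------------------------------


def build_plate_designs(sheet: SampleSheet) -> list:
    """The three audit designs the replicate-plate layout was built for.

    * ``group1`` (across-array): two subjects, four pooled replicates each,
      every replicate on a different slide;
    * ``group2`` (same-array): the same two subjects, four independently
      prepared replicates each, all eight samples on one shared slide;
    * ``null``: two further subjects, each represented twice on both sides,
      with the sides split along low (1, 2) vs high (7, 8) chamber numbers
      so positional bias shows up as false positives.
    """
    frame = sheet.frame

    # same-array pair: a slide carrying >= 4 independent replicates of each
    # of exactly two subjects
    ind = frame[~frame["pooled"]]
    pair = None
    for slide, grp in ind.groupby("slide"):
        counts = grp["subject"].value_counts()
        if len(counts) == 2 and (counts >= 4).all():
            pair = tuple(sorted(counts.index))
            pair_slide = slide
            break
    if pair is None:
        raise DesignError("no slide carries 4+4 independent replicates of two subjects")
    s1, s2 = pair
    on_slide = ind[ind["slide"] == pair_slide]
    group2 = AuditDesign(
        comparison_id="group2_same_array",
        group_a=list(on_slide[on_slide["subject"] == s1]["sample_id"][:4]),
        group_b=list(on_slide[on_slide["subject"] == s2]["sample_id"][:4]),
        audit_kind="consistency_pair",
        layout_note=f"subjects {s1} vs {s2}, all replicates on slide {pair_slide}",
        pair_id=f"{s1}_vs_{s2}",
    )

    # across-array arm: pooled replicates of the same subjects on 4 distinct slides
    pooled = frame[frame["pooled"]]

    def across(subject: str) -> list:
        picks, seen = [], set()
        for _, row in pooled[pooled["subject"] == subject].iterrows():
            if row["slide"] not in seen:
                picks.append(row["sample_id"])
                seen.add(row["slide"])
            if len(picks) == 4:
                return picks
        raise DesignError(f"subject {subject}: fewer than 4 pooled slides")

    group1 = AuditDesign(
        comparison_id="group1_across_arrays",
        group_a=across(s1),
        group_b=across(s2),
        audit_kind="consistency_pair",
        layout_note=f"subjects {s1} vs {s2}, each replicate on a different slide",
        pair_id=f"{s1}_vs_{s2}",
    )

    # null design over two other subjects (fall back to the pair if only two):
    # all side-A samples sit in chamber 1, all side-B samples in chamber 8,
    # so the comparison is fully confounded with chamber number
    others = sorted(set(frame["subject"]) - {s1, s2})
    null_subjects = others[:2] if len(others) >= 2 else [s1, s2]

    def in_chamber(subject: str, chamber: int, k: int = 2) -> list:
        sel = frame[(frame["subject"] == subject) & (frame["chamber"] == chamber)]
        if len(sel) < k:
            raise DesignError(
                f"subject {subject}: fewer than {k} replicates in chamber {chamber}"
            )
        return list(sel["sample_id"][:k])

    side_a, side_b = [], []
    for subject in null_subjects:
        side_a += in_chamber(subject, 1)
        side_b += in_chamber(subject, 8)
    null = AuditDesign(
        comparison_id="null_chamber_split",
        group_a=side_a,
        group_b=side_b,
        audit_kind="null",
        layout_note=(
            f"subjects {null_subjects} twice per side; side A entirely in "
            "chamber 1, side B entirely in chamber 8"
        ),
    )
    return [group1, group2, null]
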