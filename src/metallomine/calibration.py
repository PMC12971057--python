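"""Bitscore cutoff calibration from labeled score distributions.

Given bitscores of known-true and known-false matches for a profile, a
cutoff is chosen only when the two distributions separate cleanly:

* no negative scores at all -> cutoff = min(positive)/2 (generous margin);
* min(positive) > max(negative) -> cutoff = midpoint of the gap;
* otherwise the profile is flagged inseparable and no cutoff is emitted —
  in practice that means the profile's seed alignment needs enrichment with
  low-scoring true hits and rebuilding, a human-in-the-loop step outside
  this module.

The midpoint rule is a deterministic stand-in for manual cutoff judgment:
it maximizes the margin symmetrically and perfectly separates the training
scores by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["LabeledScores", "CutoffDecision", "choose_cutoff",
           "calibrate_table", "read_labeled_scores", "write_cutoffs"]


@dataclass(frozen=True)
class LabeledScores:
    profile: str
    positive_scores: tuple[float, ...]
    negative_scores: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.positive_scores:
            raise ValueError(f"profile {self.profile}: no positive scores")
        for s in (*self.positive_scores, *self.negative_scores):
            if not (s == s and abs(s) != float("inf")):
                raise ValueError(f"profile {self.profile}: non-finite score")


@dataclass(frozen=True)
class CutoffDecision:
    profile: str
    cutoff: float | None
    separable: bool
    gap: float | None  # min(positive) - max(negative), when both exist


def choose_cutoff(s: LabeledScores) -> CutoffDecision:
    """Pick a bitscore cutoff for one profile, or flag it inseparable."""
    lo_pos = min(s.positive_scores)
    if not s.negative_scores:
        return CutoffDecision(s.profile, lo_pos / 2, separable=True, gap=None)
    hi_neg = max(s.negative_scores)
    if lo_pos > hi_neg:
        return CutoffDecision(
            s.profile, (lo_pos + hi_neg) / 2, separable=True, gap=lo_pos - hi_neg
        )
    return CutoffDecision(s.profile, None, separable=False, gap=lo_pos - hi_neg)


def read_labeled_scores(path: str | Path) -> list[LabeledScores]:
    """Read a TSV of (profile, score, label) with label in {positive, negative}."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["profile", "score", "label"],
        dtype={"profile": str, "score": float, "label": str},
    )
    bad = set(df["label"]) - {"positive", "negative"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    out = []
    for profile, grp in df.groupby("profile", sort=True):
        pos = tuple(grp.loc[grp["label"] == "positive", "score"])
        neg = tuple(grp.loc[grp["label"] == "negative", "score"])
        out.append(LabeledScores(profile, pos, neg))
    return out


def calibrate_table(scores: list[LabeledScores]) -> list[CutoffDecision]:
    return [choose_cutoff(s) for s in scores]


def write_cutoffs(decisions: list[CutoffDecision], path: str | Path) -> None:
    """Write registry-compatible cutoff TSV (inseparable profiles commented)."""
    with open(path, "w") as fh:
        fh.write("# profile\tcutoff\tseparable\tgap\n")
        for d in decisions:
            gap = "" if d.gap is None else f"{d.gap:g}"
            if d.separable:
                fh.write(f"{d.profile}\t{d.cutoff:g}\ttrue\t{gap}\n")
            else:
                fh.write(f"# {d.profile}\tNA\tfalse\t{gap}\n")
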