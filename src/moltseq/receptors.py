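"""GPCR triage from multi-tool transmembrane-helix predictions.

Candidate receptors are genes of the GPCR signaling pathway that carry
the molecular-function annotation "G protein-coupled receptor activity"
(GO:0004930).  Their proteins are then screened structurally: a protein
is called a GPCR when at least two prediction tools (e.g. TMHMM, PSIPRED,
SWISS-MODEL) report exactly seven transmembrane helices.

Two normalizations are applied to raw tool output before counting:
segments whose reported probability falls below 0.5 are discarded
(hydrophobicity-driven over-predictions such as a spurious N-terminal
helix), and homology models built as homo-multimers ("7x2" = 7 helices
per chain, 2 chains) are reduced to their per-protomer count.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GPCR_ACTIVITY_TERM",
    "TmSegment",
    "TmPrediction",
    "GpcrCall",
    "effective_tmh_count",
    "classify_gpcr",
    "filter_gpcr_candidates",
    "read_tm_predictions",
    "write_gpcr_calls",
]

GPCR_ACTIVITY_TERM = "GO:0004930"


@dataclass(frozen=True)
class TmSegment:
    start_aa: int
    end_aa: int
    probability: float | None = None


@dataclass
class TmPrediction:
    """One tool's transmembrane-helix report for one protein."""

    protein_id: str
    tool: str
    raw_count: int
    segments: list[TmSegment] = field(default_factory=list)
    protomer_multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.raw_count < 0:
            raise ValueError("raw_count must be >= 0")
        if self.protomer_multiplicity < 1:
            raise ValueError("protomer_multiplicity must be >= 1")
        if self.segments and len(self.segments) != self.raw_count:
            raise ValueError(
                f"{self.protein_id}/{self.tool}: raw_count {self.raw_count} "
                f"!= {len(self.segments)} segments"
            )
        for s in self.segments:
            if s.probability is not None and not (0.0 <= s.probability <= 1.0):
                raise ValueError("segment probability must lie in [0, 1]")


@dataclass
class GpcrCall:
    protein_id: str
    per_tool_effective_counts: dict[str, int]
    n_tools_at_7: int
    is_gpcr: bool
    evidence_note: str


def effective_tmh_count(prediction: TmPrediction, prob_threshold: float = 0.5) -> int:
    """Helix count after probability filtering and protomer reduction.

    When per-segment probabilities are available, only segments with
    probability >= ``prob_threshold`` count (segments without a
    probability are kept).  Multimeric reports are divided by the chain
    multiplicity; a count that does not divide evenly is kept as reported
    with a warning.
    """
    if prediction.segments and any(s.probability is not None for s in prediction.segments):
        count = sum(
            1 for s in prediction.segments
            if s.probability is None or s.probability >= prob_threshold
        )
    else:
        count = prediction.raw_count
    mult = prediction.protomer_multiplicity
    if mult > 1:
        if count % mult == 0:
            count //= mult
        else:
            warnings.warn(
                f"{prediction.protein_id}/{prediction.tool}: helix count {count} "
                f"not divisible by multiplicity {mult}; keeping raw count"
            )
    return count


def classify_gpcr(
    predictions: Sequence[TmPrediction], prob_threshold: float = 0.5
) -> GpcrCall:
    """Consensus GPCR call from one protein's per-tool predictions.

    ``is_gpcr`` is true iff at least two tools have an effective count of
    exactly seven helices.  Duplicate tool entries are deduplicated (last
    wins, with a warning); a protein assessed by fewer than two tools is
    flagged "insufficient evidence" and never qualifies.
    """
    if not predictions:
        raise ValueError("classify_gpcr requires at least one prediction")
    protein_ids = {p.protein_id for p in predictions}
    if len(protein_ids) != 1:
        raise ValueError(f"predictions span several proteins: {sorted(protein_ids)}")
    by_tool: dict[str, TmPrediction] = {}
    for p in predictions:
        if p.tool in by_tool:
            warnings.warn(f"{p.protein_id}: duplicate prediction for {p.tool}; last wins")
        by_tool[p.tool] = p
    counts = {tool: effective_tmh_count(p, prob_threshold) for tool, p in by_tool.items()}
    n_at_7 = sum(1 for c in counts.values() if c == 7)
    if len(counts) < 2:
        return GpcrCall(predictions[0].protein_id, counts, n_at_7, False,
                        "insufficient evidence (<2 tools reporting)")
    is_gpcr = n_at_7 >= 2
    note = f"{n_at_7}/{len(counts)} tools at 7 TMHs"
    return GpcrCall(predictions[0].protein_id, counts, n_at_7, is_gpcr, note)


def filter_gpcr_candidates(
    genes: Sequence[str],
    gene2terms: dict[str, set[str]],
    activity_term: str = GPCR_ACTIVITY_TERM,
) -> list[str]:
    """Keep genes annotated with GPCR activity (GO:0004930), input order."""
    return [g for g in genes if activity_term in gene2terms.get(g, set())]


_COUNT_RE = re.compile(r"^\s*(\d+)\s*(?:[x×]\s*(\d+))?\s*$")


def parse_count(text: str) -> tuple[int, int]:
    """Parse a helix count, supporting multimer syntax ``7x2`` / ``7× 2``.

    Returns ``(total_count, multiplicity)`` where the total is helices
    per chain times chains (``"7x2" -> (14, 2)``).
    """
    m = _COUNT_RE.match(str(text))
    if not m:
        raise ValueError(f"cannot parse TMH count {text!r}")
    per_chain = int(m.group(1))
    mult = int(m.group(2)) if m.group(2) else 1
    return per_chain * mult, mult


def read_tm_predictions(path: str | Path) -> pd.DataFrame:
    """Read a normalized per-tool prediction table.

    Long-format TSV with at least ``protein_id``, ``tool`` and ``count``
    columns; ``count`` accepts the multimer syntax.  Extra columns
    (``comparison``, ``gene_name``, ...) are carried through.  The
    returned frame adds ``raw_count`` and ``protomer_multiplicity``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"protein_id", "tool", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    parsed = [parse_count(c) for c in df["count"]]
    df["raw_count"] = [c for c, _ in parsed]
    df["protomer_multiplicity"] = [m for _, m in parsed]
    return df


def predictions_from_frame(df: pd.DataFrame) -> dict[str, list[TmPrediction]]:
    """Group a prediction table into per-protein ``TmPrediction`` lists."""
    out: dict[str, list[TmPrediction]] = {}
    for _, r in df.iterrows():
        out.setdefault(r["protein_id"], []).append(
            TmPrediction(
                protein_id=r["protein_id"],
                tool=r["tool"],
                raw_count=int(r["raw_count"]),
                protomer_multiplicity=int(r["protomer_multiplicity"]),
            )
        )
    return out


def write_gpcr_calls(calls: Iterable[GpcrCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "protein_id": c.protein_id,
                "per_tool_counts": ";".join(
                    f"{t}={n}" for t, n in sorted(c.per_tool_effective_counts.items())
                ),
                "n_tools_at_7": c.n_tools_at_7,
                "is_gpcr": c.is_gpcr,
                "evidence_note": c.evidence_note,
            }
        )
    pd.DataFrame(
        rows, columns=["protein_id", "per_tool_counts", "n_tools_at_7",
                       "is_gpcr", "evidence_note"]
    ).to_csv(path, sep="\t", index=False)
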