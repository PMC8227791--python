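"""Cluster affinity scores by weak/strong mask and compare peptides.

Each scored duplex is assigned to the cluster of its W/S mask and the
clusters are summarised (count, mean, sample SD, best = minimum score,
and the written strand achieving it), giving the per-mask distribution
table a docking study reports.  Two keying policies are exposed:

``as_written``
    Key by the mask of the *written* strand of each record.  This is how
    docking output is naturally tabulated — the engine reports one strand
    per complex — and it can split a duplex's two strand readings of the
    same base-pair sequence into reversed mask labels.

``canonical``
    Key by the mask of the canonical strand, giving a deterministic
    labelling that is independent of which strand a file happened to
    list.

On top of the summary sit the best-complex lookup, the mask-coincidence
probability ((1/2)**k: the chance two independently chosen length-k W/S
masks agree exactly), and a two-peptide comparison reporting per-mask
mean differences and whether the best complexes share a mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hexamask.affinity_model import ScoreTable
from hexamask.duplex_space import mask_of, validate_mask, validate_strand

__all__ = [
    "MaskSummaryRow",
    "MaskSummaryTable",
    "PeptideComparison",
    "best_complex",
    "coincidence_probability",
    "compare_peptides",
    "format_probability",
    "read_summary_table",
    "summarize_by_mask",
    "write_summary_table",
]

KEYING_POLICIES = ("as_written", "canonical")


@dataclass(frozen=True)
class MaskSummaryRow:
    """Aggregate of one mask cluster: n, mean, SD, best score + sequence.

    ``n`` may be None for rows transcribed from a published summary that
    does not print cluster sizes.
    """

    mask: str
    n: int | None
    mean_score: float
    std_score: float
    best_score: float
    best_sequence: str

    def __post_init__(self) -> None:
        validate_mask(self.mask)
        validate_strand(self.best_sequence)
        if self.n is not None and self.n < 1:
            raise ValueError(f"cluster size must be >= 1, got {self.n}")
        if self.best_score > self.mean_score + 1e-9:
            raise ValueError(
                f"best (minimum) score {self.best_score} exceeds mean "
                f"{self.mean_score} for mask {self.mask}"
            )


@dataclass
class MaskSummaryTable:
    """Per-mask summary rows for one peptide, sorted by mean ascending.

    Ties on mean are broken by mask lexicographic order so the sort is
    total and runs are byte-stable.
    """

    peptide_id: str
    rows: list[MaskSummaryRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        masks = [r.mask for r in self.rows]
        if len(set(masks)) != len(masks):
            dupes = sorted({m for m in masks if masks.count(m) > 1})
            raise ValueError(f"duplicate mask rows: {dupes}")
        self.rows.sort(key=lambda r: (r.mean_score, r.mask))

    @property
    def k(self) -> int:
        if not self.rows:
            raise ValueError("empty summary table has no k")
        return len(self.rows[0].mask)

    @property
    def total_n(self) -> int:
        """Sum of known cluster sizes (rows with n=None contribute 0)."""
        return sum(r.n for r in self.rows if r.n is not None)

    def row_for(self, mask: str) -> MaskSummaryRow:
        for r in self.rows:
            if r.mask == mask:
                return r
        raise KeyError(f"no row for mask {mask}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


@dataclass(frozen=True)
class PeptideComparison:
    """Side-by-side comparison of two per-mask summaries."""

    peptide_a: str
    peptide_b: str
    shared_masks: int
    mean_differences: tuple[tuple[str, float], ...]  # (mask, mean_a - mean_b)
    best_masks_identical: bool
    best_sequences: tuple[str, str]
    best_scores: tuple[float, float]
    best_masks: tuple[str, str]


def summarize_by_mask(table: ScoreTable, keying: str = "as_written") -> MaskSummaryTable:
    """Group a score table into mask clusters and aggregate each.

    Every record lands in exactly one cluster (cluster sizes sum to the
    record count).  Mean and sample SD (ddof=1; size-1 clusters report
    0) summarise the cluster; best is the minimum score, with ties on
    the minimum broken by lexicographically smallest sequence.
    """
    if keying not in KEYING_POLICIES:
        raise ValueError(f"keying must be one of {KEYING_POLICIES}, got {keying!r}")
    if not table.records:
        raise ValueError("cannot summarize an empty score table")

    clusters: dict[str, list] = {}
    for rec in table:
        strand = rec.written_strand if keying == "as_written" else rec.duplex.canonical
        clusters.setdefault(mask_of(strand), []).append((rec.score, strand))

    rows = []
    for mask, members in clusters.items():
        scores = np.array([s for s, _ in members])
        best_score, best_sequence = min(members)  # (score, seq): lexicographic tiebreak
        rows.append(
            MaskSummaryRow(
                mask=mask,
                n=len(members),
                mean_score=float(scores.mean()),
                std_score=float(scores.std(ddof=1)) if len(members) > 1 else 0.0,
                best_score=float(best_score),
                best_sequence=best_sequence,
            )
        )
    summary = MaskSummaryTable(peptide_id=table.peptide_id, rows=rows)
    assert summary.total_n == len(table.records), "cluster sizes must sum to input"
    return summary


def best_complex(summary: MaskSummaryTable) -> tuple[str, float, str]:
    """Global best (minimum-score) complex: (sequence, score, mask).

    Ties on the minimum score are broken by lexicographically smallest
    sequence.
    """
    if not summary.rows:
        raise ValueError("empty summary table")
    best = min(summary.rows, key=lambda r: (r.best_score, r.best_sequence))
    return best.best_sequence, best.best_score, best.mask


def coincidence_probability(length: int) -> float:
    """Probability that two independent length-k W/S masks coincide.

    Each of the ``length`` positions matches with probability 1/2, so
    the probability is exactly ``(1/2)**length`` — 0.015625 for
    hexamers, conventionally reported as 0.0156.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    return 0.5**length


def format_probability(p: float, decimals: int = 4) -> str:
    """Round a probability for display (0.015625 -> '0.0156')."""
    return f"{p:.{decimals}f}"


def compare_peptides(a: MaskSummaryTable, b: MaskSummaryTable) -> PeptideComparison:
    """Compare two per-mask summaries of the same duplex length.

    Reports, for every mask present in both tables, the mean-score
    difference (a minus b; negative = a binds more strongly), plus the
    two best complexes and whether they share a mask.
    """
    if not a.rows or not b.rows:
        raise ValueError("cannot compare empty summary tables")
    if a.k != b.k:
        raise ValueError(f"mask length mismatch: {a.k} vs {b.k}")
    b_by_mask = {r.mask: r for r in b.rows}
    diffs = tuple(
        (r.mask, r.mean_score - b_by_mask[r.mask].mean_score)
        for r in a.rows
        if r.mask in b_by_mask
    )
    seq_a, score_a, mask_a = best_complex(a)
    seq_b, score_b, mask_b = best_complex(b)
    return PeptideComparison(
        peptide_a=a.peptide_id,
        peptide_b=b.peptide_id,
        shared_masks=len(diffs),
        mean_differences=diffs,
        best_masks_identical=mask_a == mask_b,
        best_sequences=(seq_a, seq_b),
        best_scores=(score_a, score_b),
        best_masks=(mask_a, mask_b),
    )


_SUMMARY_HEADER = ["mask", "n", "mean", "std", "best_score", "best_sequence"]


def write_summary_table(summary: MaskSummaryTable, path: str | Path) -> None:
    """Write a summary as tab-separated text; byte-stable for fixed input."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# peptide: " + summary.peptide_id + "\n")
        fh.write("\t".join(_SUMMARY_HEADER) + "\n")
        for r in summary:
            n = "NA" if r.n is None else str(r.n)
            fh.write(
                f"{r.mask}\t{n}\t{r.mean_score:.6f}\t{r.std_score:.6f}\t"
                f"{r.best_score:.6f}\t{r.best_sequence}\n"
            )


def read_summary_table(path: str | Path, peptide_id: str | None = None) -> MaskSummaryTable:
    """Read a summary written by :func:`write_summary_table` (or a fixture
    in the same layout)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    pid = peptide_id
    rows = []
    header_seen = False
    for line in lines:
        if line.startswith("# peptide:"):
            if pid is None:
                pid = line.split(":", 1)[1].strip()
            continue
        if not line.strip():
            continue
        cells = line.split("\t")
        if not header_seen:
            if [c.strip().lower() for c in cells] != _SUMMARY_HEADER:
                raise ValueError(f"{path}: unexpected header {cells}")
            header_seen = True
            continue
        mask, n, mean, std, best, seq = cells
        rows.append(
            MaskSummaryRow(
                mask=mask,
                n=None if n.strip().upper() == "NA" else int(n),
                mean_score=float(mean),
                std_score=float(std),
                best_score=float(best),
                best_sequence=seq.strip(),
            )
        )
    if pid is None:
        raise ValueError(f"{path}: no peptide id in file or argument")
    if not rows:
        raise ValueError(f"{path}: no summary rows")
    return MaskSummaryTable(peptide_id=pid, rows=rows)
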