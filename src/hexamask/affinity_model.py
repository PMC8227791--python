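"""Per-duplex affinity score tables and a calibrated synthetic score model.

Scores are dimensionless docking-style affinities where lower means
stronger predicted binding.  Real score tables (one score per duplex, as
produced by a docking engine) are ingested from tab-separated files;
when no docking output is available, :func:`simulate_scores` provides a
generative stand-in,

    score_i = beta0 + beta_gc * gc_count_i + mask_effect(mask_i) + eps_i,
    eps_i ~ Normal(0, sigma^2),

a linear model in the G+C content of the duplex with optional per-mask
offsets.  The default calibration is anchored to the observed range of
tripeptide-hexamer docking summaries: an intercept near the mean score
of the all-A/T mask, a negative per-G/C-base slope (higher GC content
binds more strongly), and homoscedastic Gaussian noise with a standard
deviation in the 2-3.5 range typical of per-mask dispersions.

Scores attach to *duplexes* (canonical identity), never to written
strands: a file listing both GAGTGG and CCACTC describes the same
physical duplex twice and is rejected.  The written strand is kept as
metadata for display and for mask-keying policy downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from hexamask.duplex_space import Duplex, canonicalize, mask_of, validate_mask

__all__ = [
    "ScoreModelParams",
    "ScoreRecord",
    "ScoreTable",
    "fit_gc_slope",
    "load_score_table",
    "save_score_table",
    "simulate_scores",
    "EDR_LIKE_PARAMS",
    "KED_LIKE_PARAMS",
]


@dataclass(frozen=True)
class ScoreRecord:
    """One (peptide, duplex) affinity score; lower = stronger binding."""

    peptide_id: str
    written_strand: str
    duplex: Duplex
    score: float

    def __post_init__(self) -> None:
        if canonicalize(self.written_strand) != self.duplex:
            raise ValueError(
                f"written strand {self.written_strand} does not belong to duplex "
                f"{self.duplex.canonical}"
            )
        if not math.isfinite(self.score):
            raise ValueError(f"score must be finite, got {self.score}")


@dataclass
class ScoreTable:
    """A collection of per-duplex scores for one peptide.

    At most one record per duplex; all duplexes share the same length.
    A table covering every duplex of its length (2080 for hexamers) is
    flagged complete.
    """

    peptide_id: str
    records: list[ScoreRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[Duplex, str] = {}
        k = None
        for rec in self.records:
            if rec.peptide_id != self.peptide_id:
                raise ValueError(
                    f"record peptide {rec.peptide_id!r} != table peptide "
                    f"{self.peptide_id!r}"
                )
            if k is None:
                k = rec.duplex.k
            elif rec.duplex.k != k:
                raise ValueError(
                    f"mixed duplex lengths: {k} and {rec.duplex.k} "
                    f"({rec.written_strand})"
                )
            if rec.duplex in seen:
                raise ValueError(
                    f"duplicate duplex {rec.duplex.canonical}: strands "
                    f"{seen[rec.duplex]} and {rec.written_strand} are "
                    "reverse complements of each other"
                )
            seen[rec.duplex] = rec.written_strand

    @property
    def k(self) -> int:
        if not self.records:
            raise ValueError("empty score table has no k")
        return self.records[0].duplex.k

    @property
    def is_complete(self) -> bool:
        """True iff every duplex of length k is scored."""
        from hexamask.duplex_space import duplex_space_size

        return bool(self.records) and len(self.records) == duplex_space_size(self.k)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class ScoreModelParams:
    """Parameters of the synthetic linear score model.

    beta0
        Intercept: expected score of a duplex with zero G/C bases.
    beta_gc
        Per-G/C-base slope; negative means GC-rich duplexes bind
        more strongly (lower score).
    mask_effects
        Optional additive offset per weak/strong mask (keyed by the
        mask of the canonical strand); default none.
    sigma
        Standard deviation of the Gaussian noise; >= 0.
    seed
        Seed for the noise stream; identical seed gives an identical
        table.
    """

    beta0: float = -31.76
    beta_gc: float = -0.925
    mask_effects: tuple[tuple[str, float], ...] = ()
    sigma: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if isinstance(self.mask_effects, dict):
            object.__setattr__(
                self, "mask_effects", tuple(sorted(self.mask_effects.items()))
            )
        for mask, _ in self.mask_effects:
            validate_mask(mask)

    def mask_effect(self, mask: str) -> float:
        return dict(self.mask_effects).get(mask, 0.0)


# Default calibrations for the two tripeptides the toolkit was built
# around.  EDR (Glu-Asp-Arg): intercept at the all-W mean, slope set so
# the all-S mean sits ~5.5 score units lower over 6 G/C bases.  KED
# (Lys-Glu-Asp): weaker overall binding and a much flatter GC trend.
EDR_LIKE_PARAMS = ScoreModelParams(beta0=-31.76, beta_gc=-0.925, sigma=2.5)
KED_LIKE_PARAMS = ScoreModelParams(beta0=-12.50, beta_gc=-0.047, sigma=3.5)


def simulate_scores(
    params: ScoreModelParams,
    duplexes: list[Duplex],
    peptide_id: str = "SIM",
) -> ScoreTable:
    """Draw one synthetic score per duplex from the linear model.

    Deterministic given ``params.seed``; duplexes are scored in sorted
    canonical order so the noise stream does not depend on input order.
    """
    if not duplexes:
        raise ValueError("no duplexes to score")
    ks = {d.k for d in duplexes}
    if len(ks) > 1:
        raise ValueError(f"duplexes of mixed lengths {sorted(ks)}")
    k = ks.pop()
    for mask, _ in params.mask_effects:
        if len(mask) != k:
            raise ValueError(
                f"mask_effects key {mask!r} has length {len(mask)}, expected {k}"
            )
    ordered = sorted(set(duplexes))
    rng = np.random.default_rng(params.seed)
    noise = rng.normal(0.0, params.sigma, size=len(ordered)) if params.sigma > 0 else (
        np.zeros(len(ordered))
    )
    records = [
        ScoreRecord(
            peptide_id=peptide_id,
            written_strand=d.canonical,
            duplex=d,
            score=float(params.beta0 + params.beta_gc * d.gc_count
                        + params.mask_effect(d.mask) + eps),
        )
        for d, eps in zip(ordered, noise)
    ]
    return ScoreTable(peptide_id=peptide_id, records=records)


def load_score_table(path: str | Path, peptide_id: str | None = None) -> ScoreTable:
    """Read a tab-separated score table.

    Expected layout: a header line, then one row per duplex with columns
    ``peptide``, ``strand``, ``score`` (or just ``strand``, ``score``
    with the peptide given as an argument).  Strands are validated and
    canonicalized; two strands mapping to the same duplex are a hard
    error naming both.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty score table file")
    header = [c.strip().lower() for c in lines[0].split("\t")]
    try:
        strand_col = header.index("strand")
        score_col = header.index("score")
    except ValueError:
        raise ValueError(
            f"{path}: header must contain 'strand' and 'score' columns, got {header}"
        ) from None
    pep_col = header.index("peptide") if "peptide" in header else None

    records: list[ScoreRecord] = []
    pid = peptide_id
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} columns")
        strand = cells[strand_col].strip()
        try:
            score = float(cells[score_col])
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: malformed score {cells[score_col]!r}"
            ) from None
        row_pid = cells[pep_col].strip() if pep_col is not None else pid
        if row_pid is None:
            raise ValueError(
                f"{path}: no peptide column and no peptide_id argument given"
            )
        if pid is None:
            pid = row_pid
        elif row_pid != pid:
            raise ValueError(
                f"{path}:{lineno}: mixed peptides {pid!r} and {row_pid!r} in one table"
            )
        records.append(
            ScoreRecord(
                peptide_id=pid,
                written_strand=strand.upper(),
                duplex=canonicalize(strand),
                score=score,
            )
        )
    if not records:
        raise ValueError(f"{path}: score table has a header but no records")
    return ScoreTable(peptide_id=pid, records=records)


def save_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a table in the same tab-separated layout load expects."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("peptide\tstrand\tscore\n")
        for rec in table:
            fh.write(f"{rec.peptide_id}\t{rec.written_strand}\t{rec.score!r}\n")


def fit_gc_slope(table: ScoreTable) -> tuple[float, float]:
    """Ordinary least-squares slope of score on G+C count, with its SE.

    Quantifies the GC-affinity trend; also the parameter-recovery check
    for the synthetic model.  Requires at least 3 distinct GC counts.
    """
    if not table.records:
        raise ValueError("empty score table")
    gc = np.array([rec.duplex.gc_count for rec in table], dtype=float)
    scores = np.array([rec.score for rec in table], dtype=float)
    if len(np.unique(gc)) < 3:
        raise ValueError(
            f"need >= 3 distinct GC counts to fit a slope, got {len(np.unique(gc))}"
        )
    res = stats.linregress(gc, scores)
    stderr = float(res.stderr) if math.isfinite(res.stderr) else 0.0
    return float(res.slope), stderr
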