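"""Synthetic inputs with known ground truth, plus packaged reference tables.

Two kinds of data feed the pipeline when real inputs are unavailable:

* synthetic promoter sequences — i.i.d. background at a chosen GC
  fraction with motif occurrences *planted* at known positions, post-
  verified against an independent brute-force counter so the planted
  count is exact across all four strand/orientation variants;

* synthetic score tables from the affinity model (see
  :mod:`hexamask.affinity_model`).

The package also ships hand-transcribed reference tables from a
published tripeptide-dsDNA docking study: per-mask score summaries for
the EDR and KED tripeptides (48 mask rows each) and promoter occurrence
counts of the low-energy masks in Alzheimer's-disease-related genes.
The transcriptions are data, not computation — the docking engine and
the promoter-database snapshot behind them are not reproducible here —
and are integrity-checked against shipped SHA-256 checksums on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from hexamask.affinity_model import (
    EDR_LIKE_PARAMS,
    KED_LIKE_PARAMS,
    ScoreModelParams,
    save_score_table,
    simulate_scores,
)
from hexamask.duplex_space import enumerate_duplexes, reverse_complement, validate_strand
from hexamask.mask_aggregation import MaskSummaryTable, read_summary_table
from hexamask.promoter_scan import (
    Needle,
    PromoterRecord,
    ScanPolicy,
    compile_variants,
    count_occurrences,
    scan,
)

__all__ = [
    "AD_GENES",
    "FixtureSet",
    "PlantSpec",
    "Table2Entry",
    "generate_promoter",
    "load_fixtures",
    "make_demo_bundle",
]

#: Alzheimer's-disease-related genes whose promoters the reference study scanned.
AD_GENES = (
    "CASP3", "TP53", "SOD2", "GPX1", "PPARA", "PPARG",
    "NES", "GAP43", "SUMO1", "APOE", "IGF1",
)


@dataclass(frozen=True)
class PlantSpec:
    """A motif to plant in a synthetic promoter.

    positions are 1-based starts on the chosen variant; when omitted,
    non-overlapping positions are drawn at random.
    """

    needle: str
    count: int
    variant: str = "original"
    positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        validate_strand(self.needle)
        if self.count < 0:
            raise ValueError("plant count must be >= 0")
        if self.positions:
            if len(self.positions) != self.count:
                raise ValueError(
                    f"{len(self.positions)} positions given for count {self.count}"
                )
            starts = sorted(self.positions)
            for a, b in zip(starts, starts[1:]):
                if b < a + len(self.needle):
                    raise ValueError(f"planted windows at {a} and {b} overlap")
        if self.variant not in ("original", "complement", "reverse", "reverse_complement"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class Table2Entry:
    """One reference occurrence record: mask x gene -> printed count."""

    entry: int
    mean_score: float
    mask: str
    gene: str
    count: int


@dataclass
class FixtureSet:
    """Packaged reference tables and the study's gene list."""

    table1_edr: MaskSummaryTable
    table1_ked: MaskSummaryTable
    table2: list[Table2Entry] = field(default_factory=list)
    genes: tuple[str, ...] = AD_GENES


def _data_path(name: str) -> Path:
    return Path(str(resources.files("hexamask").joinpath("data", name)))


def load_fixtures(verify_checksums: bool = True) -> FixtureSet:
    """Load the packaged reference tables.

    Verifies each file against its shipped SHA-256 checksum (the
    transcriptions are the only bridge to the unpublishable docking
    output, so silent corruption must be loud).
    """
    checksums = json.loads(_data_path("checksums.json").read_text())
    names = ("table1_edr.tsv", "table1_ked.tsv", "table2_occurrences.tsv")
    if verify_checksums:
        for name in names:
            digest = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
            if digest != checksums.get(name):
                raise ValueError(
                    f"fixture {name} checksum mismatch: file is corrupted or edited"
                )
    edr = read_summary_table(_data_path("table1_edr.tsv"))
    ked = read_summary_table(_data_path("table1_ked.tsv"))

    table2: list[Table2Entry] = []
    for line in _data_path("table2_occurrences.tsv").read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        cells = line.split("\t")
        if cells[0] == "entry":
            continue
        entry, mean, mask, gene, count = cells
        table2.append(
            Table2Entry(
                entry=int(entry),
                mean_score=float(mean),
                mask=mask,
                gene=gene,
                count=int(count),
            )
        )
    if len(edr) != 48 or len(ked) != 48:
        raise ValueError(
            f"expected 48 mask rows per peptide, got {len(edr)} EDR / {len(ked)} KED"
        )
    if len({e.entry for e in table2}) != 9:
        raise ValueError("expected 9 reference mask entries in the occurrence table")
    return FixtureSet(table1_edr=edr, table1_ked=ked, table2=table2)


def _draw_background(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    p = np.array([
        (1 - gc_fraction) / 2,  # A
        gc_fraction / 2,        # C
        gc_fraction / 2,        # G
        (1 - gc_fraction) / 2,  # T
    ])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def generate_promoter(
    length: int,
    gc_fraction: float = 0.5,
    plants: list[PlantSpec] | None = None,
    seed: int = 0,
    gene: str = "SYNTH",
    max_retries: int = 100,
) -> tuple[PromoterRecord, dict[str, int]]:
    """Synthesize a promoter with exact, verified planted motif counts.

    Background bases are i.i.d. at ``gc_fraction``; each plant's needle
    is written at its (given or drawn) positions on the stated variant.
    The draw is then *verified* with the brute-force counter: the total
    occurrences of each planted needle across all four variants
    (deduplicated, overlapping) must equal exactly the planted count —
    no accidental background hits, no plants destroyed by later plants.
    Failing draws are rejected and redrawn, up to ``max_retries``.

    Returns the promoter record and the ground-truth mapping
    ``needle -> total count``.  Deterministic given ``seed``.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    plants = plants or []
    for p in plants:
        need = p.count * len(p.needle)
        if need > length:
            raise ValueError(
                f"cannot place {p.count} copies of {p.needle} in {length} bp"
            )
        if p.positions and max(p.positions) + len(p.needle) - 1 > length:
            raise ValueError(f"plant position beyond sequence end for {p.needle}")

    rng = np.random.default_rng(seed)
    policy = ScanPolicy()  # overlapping, dedup variants, all four
    for _attempt in range(max_retries):
        seq = list(_draw_background(rng, length, gc_fraction))
        occupied: set[int] = set()
        ok = True
        for p in plants:
            # write the needle so that it reads correctly on the target
            # variant: planting on 'original' writes the needle itself;
            # on the reverse complement variant, position i there maps
            # back to the original strand as the needle's rc, etc.
            written = _needle_on_original(p)
            if p.positions:
                starts = [pos - 1 for pos in p.positions]
            else:
                starts = _draw_starts(rng, length, len(written), p.count, occupied)
                if starts is None:
                    ok = False
                    break
            for s0 in starts:
                win = range(s0, s0 + len(written))
                if occupied & set(win):
                    ok = False
                    break
                seq[s0 : s0 + len(written)] = written
                occupied.update(win)
            if not ok:
                break
        if not ok:
            continue
        text = "".join(seq)
        truth: dict[str, int] = {}
        verified = True
        for p in plants:
            needle = Needle(kind="exact", pattern=p.needle)
            total = _variant_total(needle, text, policy)
            if total != p.count:
                verified = False
                break
            truth[p.needle] = total
        if verified:
            rec = PromoterRecord(
                gene=gene,
                sequence=text,
                source_id=f"synthetic seed={seed}",
                window_note=(
                    f"synthetic i.i.d. background, GC={gc_fraction}, {length} bp"
                ),
            )
            return rec, truth
    raise RuntimeError(
        f"could not generate a promoter with exact planted counts in "
        f"{max_retries} attempts (layout too constrained?)"
    )


def _needle_on_original(p: PlantSpec) -> str:
    """What to write on the original strand so the needle appears on
    the requested variant (each variant transform is an involution, and
    plant positions are interpreted on the original strand)."""
    if p.variant == "original":
        return p.needle
    if p.variant == "complement":
        from hexamask.duplex_space import complement

        return complement(p.needle)
    if p.variant == "reverse":
        return p.needle[::-1]
    return reverse_complement(p.needle)


def _draw_starts(rng, length, width, count, occupied):
    """Draw `count` non-overlapping 0-based starts avoiding occupied cells."""
    starts: list[int] = []
    taken = set(occupied)
    for _ in range(count):
        candidates = [
            s for s in range(0, length - width + 1)
            if not (taken & set(range(s, s + width)))
        ]
        if not candidates:
            return None
        s = int(rng.choice(candidates))
        starts.append(s)
        taken.update(range(s, s + width))
    return starts


def _variant_total(needle: Needle, text: str, policy: ScanPolicy) -> int:
    """Independent total across deduplicated variants (brute-force counter)."""
    variants = compile_variants(text)
    total = 0
    seen: set[str] = set()
    for name in policy.total_variants():
        v = variants[name]
        if policy.dedup_variants:
            if v in seen:
                continue
            seen.add(v)
        total += count_occurrences(needle, v, policy.overlapping)
    return total


def make_demo_bundle(out_dir: str | Path, seed: int = 0) -> Path:
    """Write a small self-contained demo input set with a manifest.

    Contents: simulated EDR-like and KED-like score tables over all 2080
    hexanucleotide duplexes, eleven synthetic promoters (600 bp, GC 0.5)
    named after the reference gene list with known planted copies of the
    two best-binding hexamers, and a JSON manifest of the expected
    planted counts.  Byte-identical for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    duplexes = enumerate_duplexes(6)

    edr_params = ScoreModelParams(
        beta0=EDR_LIKE_PARAMS.beta0,
        beta_gc=EDR_LIKE_PARAMS.beta_gc,
        sigma=EDR_LIKE_PARAMS.sigma,
        seed=seed,
    )
    ked_params = ScoreModelParams(
        beta0=KED_LIKE_PARAMS.beta0,
        beta_gc=KED_LIKE_PARAMS.beta_gc,
        sigma=KED_LIKE_PARAMS.sigma,
        seed=seed + 1,
    )
    edr_table = simulate_scores(edr_params, duplexes, peptide_id="EDR-like")
    ked_table = simulate_scores(ked_params, duplexes, peptide_id="KED-like")
    save_score_table(edr_table, out / "scores_edr_like.tsv")
    save_score_table(ked_table, out / "scores_ked_like.tsv")

    # Plant the two study best-binders at gene-dependent known counts.
    needles = ("GAGTGG", "CAGAGG")
    manifest: dict = {"seed": seed, "genes": {}, "needles": list(needles)}
    fasta_lines: list[str] = []
    for i, gene in enumerate(AD_GENES):
        counts = {needles[0]: (i % 4), needles[1]: ((i + 2) % 3)}
        plants = [PlantSpec(needle=n, count=c) for n, c in counts.items()]
        rec, truth = generate_promoter(
            length=600, gc_fraction=0.5, plants=plants, seed=seed * 1000 + i,
            gene=gene,
        )
        fasta_lines.append(f">{gene} {rec.window_note}")
        for j in range(0, len(rec.sequence), 70):
            fasta_lines.append(rec.sequence[j : j + 70])
        manifest["genes"][gene] = truth
    (out / "promoters.fasta").write_text("\n".join(fasta_lines) + "\n")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out


def verify_demo_bundle(bundle_dir: str | Path) -> bool:
    """Re-scan a demo bundle and check the manifest counts hold exactly."""
    from hexamask.promoter_scan import read_promoters

    bundle = Path(bundle_dir)
    manifest = json.loads((bundle / "manifest.json").read_text())
    promoters = read_promoters(bundle / "promoters.fasta")
    needles = [Needle(kind="exact", pattern=n) for n in manifest["needles"]]
    report = scan(needles, promoters)
    for gene, truth in manifest["genes"].items():
        for needle, expected in truth.items():
            if report.total(needle, gene) != expected:
                return False
    return True
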