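"""Promoter occurrence scanning over the four strand/orientation variants.

For each promoter sequence, four variants are compiled — the original
strand, its complement, its reverse, and its reverse complement — and
each needle is counted on every variant.  A needle is either an exact
nucleotide word or a degenerate weak/strong mask, where W matches {A, T}
and S matches {C, G} (the IUPAC W/S codes).  Matches may overlap; counts
are start positions, 1-based in reports.

Counting a needle on the reverse-complement variant equals counting the
needle's reverse complement on the original strand, so the four-variant
policy subsumes conventional two-strand scanning; the complement-only
and reverse-only variants are not biological reading frames but are kept
because some published searches compile them.  A
``biological_strands_only`` switch restricts totals to original +
reverse complement.

``N`` bases are accepted in promoters and never match any needle
position, exact or mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json
import warnings

from Bio import SeqIO

from hexamask.duplex_space import validate_mask, validate_strand

__all__ = [
    "Needle",
    "OccurrenceEntry",
    "OccurrenceReport",
    "PromoterRecord",
    "ScanPolicy",
    "VARIANT_NAMES",
    "compile_variants",
    "count_occurrences",
    "read_promoters",
    "scan",
    "write_occurrence_report",
]

VARIANT_NAMES = ("original", "complement", "reverse", "reverse_complement")
BIOLOGICAL_VARIANTS = ("original", "reverse_complement")

_MASK_MATCH = {"W": frozenset("AT"), "S": frozenset("CG")}


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter sequence with provenance."""

    gene: str
    sequence: str
    source_id: str = ""
    window_note: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be nonempty")
        object.__setattr__(
            self, "sequence", validate_strand(self.sequence, allow_n=True)
        )


@dataclass(frozen=True)
class Needle:
    """A search pattern: an exact word or a degenerate W/S mask."""

    kind: str  # "exact" | "mask"
    pattern: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind == "exact":
            object.__setattr__(self, "pattern", validate_strand(self.pattern))
        elif self.kind == "mask":
            object.__setattr__(self, "pattern", validate_mask(self.pattern))
        else:
            raise ValueError(f"needle kind must be 'exact' or 'mask', got {self.kind!r}")
        if not self.label:
            object.__setattr__(self, "label", self.pattern)

    def matches_at(self, text: str, start: int) -> bool:
        """Whether the needle matches ``text`` at 0-based offset ``start``."""
        window = text[start : start + len(self.pattern)]
        if len(window) < len(self.pattern):
            return False
        if self.kind == "exact":
            return window == self.pattern
        return all(
            base in _MASK_MATCH[sym] for sym, base in zip(self.pattern, window)
        )


@dataclass(frozen=True)
class ScanPolicy:
    """How per-variant counts combine into a total.

    overlapping
        Count overlapping matches (default true).
    dedup_variants
        Identical variant strings (e.g. original == reverse complement
        of a palindromic sequence) are counted once in the total.
    biological_strands_only
        Restrict the total to original + reverse complement.
    """

    overlapping: bool = True
    dedup_variants: bool = True
    biological_strands_only: bool = False

    def total_variants(self) -> tuple[str, ...]:
        return BIOLOGICAL_VARIANTS if self.biological_strands_only else VARIANT_NAMES


def compile_variants(s: str, dedup: bool = False) -> dict[str, str]:
    """The four labeled strand/orientation variants of a sequence.

    With ``dedup=True``, variants whose string equals an earlier variant
    are dropped (keeping the first label in VARIANT_NAMES order).
    """
    s = validate_strand(s, allow_n=True)
    comp = _complement_with_n(s)  # N complements to N
    variants = {
        "original": s,
        "complement": comp,
        "reverse": s[::-1],
        "reverse_complement": comp[::-1],
    }
    if not dedup:
        return variants
    out: dict[str, str] = {}
    seen: set[str] = set()
    for name in VARIANT_NAMES:
        if variants[name] not in seen:
            out[name] = variants[name]
            seen.add(variants[name])
    return out


_COMPLEMENT_N = str.maketrans("ACGTN", "TGCAN")


def _complement_with_n(s: str) -> str:
    return s.translate(_COMPLEMENT_N)


def count_occurrences(needle: Needle, text: str, overlapping: bool = True) -> int:
    """Number of start positions where the needle matches the text.

    Overlapping matches are counted by default; with
    ``overlapping=False`` the scan resumes after each match.  A needle
    longer than the text yields 0.
    """
    text = validate_strand(text, allow_n=True)
    m, n = len(needle.pattern), len(text)
    count = 0
    i = 0
    while i <= n - m:
        if needle.matches_at(text, i):
            count += 1
            i += 1 if overlapping else m
        else:
            i += 1
    return count


@dataclass(frozen=True)
class OccurrenceEntry:
    """Counts of one needle in one promoter, per variant and total."""

    needle_label: str
    gene: str
    variant_counts: tuple[tuple[str, int], ...]
    total: int

    def count(self, variant: str) -> int:
        return dict(self.variant_counts)[variant]


@dataclass
class OccurrenceReport:
    """Gene x needle occurrence counts with the policy that produced them."""

    entries: list[OccurrenceEntry]
    policy: ScanPolicy = field(default_factory=ScanPolicy)

    def entry(self, needle_label: str, gene: str) -> OccurrenceEntry:
        for e in self.entries:
            if e.needle_label == needle_label and e.gene == gene:
                return e
        raise KeyError(f"no entry for needle {needle_label!r} in gene {gene!r}")

    def total(self, needle_label: str, gene: str) -> int:
        return self.entry(needle_label, gene).total

    def to_json(self) -> str:
        return json.dumps(
            {
                "policy": {
                    "overlapping": self.policy.overlapping,
                    "dedup_variants": self.policy.dedup_variants,
                    "biological_strands_only": self.policy.biological_strands_only,
                },
                "entries": [
                    {
                        "needle": e.needle_label,
                        "gene": e.gene,
                        "counts": dict(e.variant_counts),
                        "total": e.total,
                    }
                    for e in self.entries
                ],
            },
            indent=2,
            sort_keys=True,
        )


def scan(
    needles: list[Needle],
    promoters: list[PromoterRecord],
    policy: ScanPolicy | None = None,
) -> OccurrenceReport:
    """Count every needle in every promoter across compiled variants.

    The per-variant breakdown is always emitted; the total combines the
    policy's variant set, counting each distinct variant string once
    when ``dedup_variants`` is set.  Rows are sorted by needle label
    then gene so reports are byte-stable.  Duplicate gene symbols are
    kept separate with ``.2``, ``.3``... suffixes and a warning.
    """
    if not needles:
        raise ValueError("no needles to scan for")
    if not promoters:
        raise ValueError("no promoters to scan")
    policy = policy or ScanPolicy()

    # Disambiguate duplicate gene symbols.
    seen_genes: dict[str, int] = {}
    labeled: list[tuple[str, PromoterRecord]] = []
    for rec in promoters:
        seen_genes[rec.gene] = seen_genes.get(rec.gene, 0) + 1
        label = rec.gene if seen_genes[rec.gene] == 1 else f"{rec.gene}.{seen_genes[rec.gene]}"
        if seen_genes[rec.gene] == 2:
            warnings.warn(f"duplicate gene symbol {rec.gene!r}; suffixing", stacklevel=2)
        labeled.append((label, rec))

    labels = [n.label for n in needles]
    if len(set(labels)) != len(labels):
        raise ValueError("needle labels must be unique")

    entries = []
    for needle in needles:
        for gene_label, rec in labeled:
            variants = compile_variants(rec.sequence)
            counts = {
                name: count_occurrences(needle, seq, policy.overlapping)
                for name, seq in variants.items()
            }
            total = 0
            seen_strings: set[str] = set()
            for name in policy.total_variants():
                if policy.dedup_variants:
                    if variants[name] in seen_strings:
                        continue
                    seen_strings.add(variants[name])
                total += counts[name]
            entries.append(
                OccurrenceEntry(
                    needle_label=needle.label,
                    gene=gene_label,
                    variant_counts=tuple(counts.items()),
                    total=total,
                )
            )
    entries.sort(key=lambda e: (e.needle_label, e.gene))
    return OccurrenceReport(entries=entries, policy=policy)


def read_promoters(
    path: str | Path,
    gene_from_header=None,
) -> list[PromoterRecord]:
    """Load promoters from FASTA.

    ``gene_from_header`` maps a FASTA header (the full description line
    without '>') to a gene symbol; the default takes the first
    whitespace-separated token.  Lowercase sequence is uppercased; any
    character outside {A, C, G, T, N} is rejected with the record index.
    """
    path = Path(path)
    if gene_from_header is None:
        gene_from_header = lambda header: header.split()[0]  # noqa: E731
    records = []
    with path.open() as fh:
        for idx, rec in enumerate(SeqIO.parse(fh, "fasta"), start=1):
            header = rec.description
            try:
                gene = gene_from_header(header)
                seq = validate_strand(str(rec.seq), allow_n=True)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: record {idx} ({header!r}): {exc}") from exc
            records.append(
                PromoterRecord(
                    gene=gene,
                    sequence=seq,
                    source_id=header,
                    window_note=f"as supplied in {path.name}",
                )
            )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_occurrence_report(report: OccurrenceReport, path: str | Path) -> None:
    """Tab-separated report: needle_label, gene, variant, count, total."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("needle_label\tgene\tvariant\tcount\ttotal\n")
        for e in report.entries:
            for variant, count in e.variant_counts:
                fh.write(f"{e.needle_label}\t{e.gene}\t{variant}\t{count}\t{e.total}\n")
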