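"""Four-variant compilation, occurrence counting, and promoter scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexamask.duplex_space import reverse_complement
from hexamask.promoter_scan import (
    Needle,
    PromoterRecord,
    ScanPolicy,
    compile_variants,
    count_occurrences,
    read_promoters,
    scan,
)

texts = st.text(alphabet="ACGT", min_size=6, max_size=60)


def _brute_force_count(needle: Needle, text: str) -> int:
    """Independent positionwise re-check (sliding window, overlapping)."""
    allowed = {"W": "AT", "S": "CG"}
    m = len(needle.pattern)
    hits = 0
    for i in range(len(text) - m + 1):
        window = text[i : i + m]
        if needle.kind == "exact":
            ok = window == needle.pattern
        else:
            ok = all(b in allowed[s] for s, b in zip(needle.pattern, window))
        hits += ok
    return hits


def test_compile_variants_examples():
    v = compile_variants("AACGT")
    assert v == {
        "original": "AACGT",
        "complement": "TTGCA",
        "reverse": "TGCAA",
        "reverse_complement": "ACGTT",
    }
    # rc palindrome: original == reverse complement AND reverse == complement,
    # so dedup keeps exactly 2 distinct strings
    v = compile_variants("GAATTC", dedup=True)
    assert v == {"original": "GAATTC", "complement": "CTTAAG"}
    v = compile_variants("AT", dedup=True)
    assert set(v.values()) == {"AT", "TA"}


def test_compile_variants_preserves_n():
    v = compile_variants("ACNGT")
    assert v["complement"] == "TGNCA"
    assert v["reverse"] == "TGNCA"
    assert v["reverse_complement"] == "ACNGT"  # self-rc once N complements to N


@pytest.mark.parametrize(
    "kind,pattern,text,expected",
    [
        ("exact", "GAGTGG", "GAGTGGAGTGG", 2),  # overlapping
        ("exact", "GAGTGG", "GAG", 0),  # needle longer than text
        ("mask", "SWSWSS", "GAGTGGAA", 1),
        ("mask", "SSSSSS", "AAAAAAAA", 0),
        ("exact", "AA", "AAAA", 3),
        ("mask", "WW", "AAAA", 3),
    ],
)
def test_count_occurrences_examples(kind, pattern, text, expected):
    assert count_occurrences(Needle(kind=kind, pattern=pattern), text) == expected


def test_non_overlapping_policy():
    assert count_occurrences(Needle(kind="exact", pattern="AA"), "AAAA",
                             overlapping=False) == 2


def test_n_bases_never_match():
    assert count_occurrences(Needle(kind="exact", pattern="GAGTGG"), "GAGNGG") == 0
    assert count_occurrences(Needle(kind="mask", pattern="SWSWSS"), "GANTGG") == 0


@settings(derandomize=True, max_examples=100)
@given(texts, st.text(alphabet="ACGT", min_size=2, max_size=6))
def test_rc_variant_count_identity(text, needle_seq):
    """Counting x on the rc variant == counting rc(x) on the original:
    the four-variant policy subsumes two-strand scanning."""
    needle = Needle(kind="exact", pattern=needle_seq)
    rc_needle = Needle(kind="exact", pattern=reverse_complement(needle_seq))
    variants = compile_variants(text)
    assert count_occurrences(needle, variants["reverse_complement"]) == (
        count_occurrences(rc_needle, variants["original"])
    )


def test_scanner_matches_brute_force_oracle():
    """Oracle equivalence on 100 random (needle, text) pairs, both kinds."""
    rng = np.random.default_rng(7)
    for trial in range(100):
        text = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 120)))
        m = int(rng.integers(2, 7))
        if trial % 2 == 0:
            needle = Needle(kind="exact",
                            pattern="".join(rng.choice(list("ACGT"), size=m)))
        else:
            needle = Needle(kind="mask",
                            pattern="".join(rng.choice(list("WS"), size=m)))
        assert count_occurrences(needle, text) == _brute_force_count(needle, text)


def test_expected_mask_hit_rate_on_uniform_sequence():
    """Mean mask-needle count over uniform sequence is (L-5)/64 within 3 SD."""
    rng = np.random.default_rng(123)
    L, n_sims = 400, 200
    needle = Needle(kind="mask", pattern="SWSWSS")
    counts = []
    for _ in range(n_sims):
        text = "".join(rng.choice(list("ACGT"), size=L))
        counts.append(count_occurrences(needle, text))
    counts = np.array(counts)
    expected = (L - 5) * 0.5**6
    sd_of_mean = counts.std(ddof=1) / np.sqrt(n_sims)
    assert abs(counts.mean() - expected) < 3 * sd_of_mean


def test_scan_report_structure_and_determinism():
    promoters = [
        PromoterRecord(gene="G1", sequence="GAGTGG" + "A" * 30),
        PromoterRecord(gene="G2", sequence="T" * 40),
    ]
    needles = [Needle(kind="exact", pattern="GAGTGG"),
               Needle(kind="mask", pattern="SSSSSS")]
    r1 = scan(needles, promoters)
    r2 = scan(needles, promoters)
    assert r1.to_json() == r2.to_json()
    entry = r1.entry("GAGTGG", "G1")
    assert entry.count("original") == 1
    # on the rc variant the word reads CCACTC, so GAGTGG is not found there
    assert entry.count("reverse_complement") == 0
    assert entry.total == 1
    assert r1.total("GAGTGG", "G2") == 0
    assert r1.total("SSSSSS", "G2") == 0
    # rows sorted by needle label then gene
    keys = [(e.needle_label, e.gene) for e in r1.entries]
    assert keys == sorted(keys)


def test_scan_biological_strands_only_policy():
    promoters = [PromoterRecord(gene="G", sequence="GAGTGG" + "A" * 20)]
    needle = Needle(kind="exact", pattern="GAGTGG")
    all4 = scan([needle], promoters, ScanPolicy())
    bio = scan([needle], promoters, ScanPolicy(biological_strands_only=True))
    assert all4.total("GAGTGG", "G") == 1
    assert bio.total("GAGTGG", "G") == 1
    # a reversal-symmetric mask hits the original and rc variants alike
    sym = Needle(kind="mask", pattern="SWWS")
    bio_sym = scan([sym], [PromoterRecord(gene="G", sequence="GATC" + "A" * 20)],
                   ScanPolicy(biological_strands_only=True))
    assert bio_sym.entry("SWWS", "G").count("original") == 1
    assert bio_sym.entry("SWWS", "G").count("reverse_complement") == 1
    assert bio_sym.total("SWWS", "G") == 2
    assert set(dict(bio.entries[0].variant_counts)) == set(
        dict(all4.entries[0].variant_counts)
    )  # per-variant breakdown always emitted


def test_scan_duplicate_gene_symbols_warn_and_suffix():
    promoters = [
        PromoterRecord(gene="G", sequence="A" * 20),
        PromoterRecord(gene="G", sequence="GAGTGG" + "A" * 20),
    ]
    with pytest.warns(UserWarning, match="duplicate gene"):
        report = scan([Needle(kind="exact", pattern="GAGTGG")], promoters)
    assert report.total("GAGTGG", "G") == 0
    assert report.total("GAGTGG", "G.2") == 1


def test_read_promoters(tmp_path):
    fasta = tmp_path / "prom.fasta"
    fasta.write_text(
        ">CASP3 promoter window\nacgtACGT\nacgt\n>TP53\nGAGTGGNNA\n"
    )
    records = read_promoters(fasta)
    assert [r.gene for r in records] == ["CASP3", "TP53"]
    assert records[0].sequence == "ACGTACGTACGT"
    assert records[1].sequence == "GAGTGGNNA"

    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    with pytest.raises(ValueError, match="no FASTA records"):
        read_promoters(empty)

    bad = tmp_path / "bad.fasta"
    bad.write_text(">X\nACGU\n")
    with pytest.raises(ValueError, match="record 1"):
        read_promoters(bad)
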