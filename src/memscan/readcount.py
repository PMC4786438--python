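"""Paired-end amplicon reads -> filtered per-variant count tables.

The quality-control pipeline: reconstruct the amplicon from the read pair
(requiring agreement wherever both reads cover the scanned span), check the
constant flanks, translate the span, keep wild-type and single amino-acid
mutants, and finally mask variants with low reference-population counts.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .constructs import Construct, VariantId
from .genetic import AMINO_ACIDS, reverse_complement, translate

#: Rejection reasons recorded in the QC report.
REJECT_REASONS = (
    "flank_mismatch",
    "overlap_conflict",
    "incomplete_coverage",
    "multi_mutant",
    "stop",
    "bad_frame",
    "low_quality",
)


@dataclass
class Reject:
    reason: str


@dataclass
class CountTable:
    """Per-(position, amino-acid) read counts for one population."""

    population: str
    counts: dict[tuple[int, str], int]
    wildtype_count: int
    wildtype: dict[int, str]
    n_reads_total: int = 0
    n_reads_passing: int = 0
    qc: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (pos, aa), c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {(pos, aa)}")
            if self.wildtype.get(pos) == aa:
                raise ValueError(
                    f"wild-type identity {(pos, aa)} must not appear in "
                    "the variant counts"
                )
        if self.wildtype_count < 0:
            raise ValueError("negative wild-type count")

    def count(self, position: int, aa: str) -> int:
        if self.wildtype.get(position) == aa:
            return self.wildtype_count
        return self.counts.get((position, aa), 0)

    @property
    def variant_universe(self) -> list[tuple[int, str]]:
        """All non-wild-type (position, aa) pairs of the scanned span."""
        return [
            (pos, aa)
            for pos in sorted(self.wildtype)
            for aa in AMINO_ACIDS
            if aa != self.wildtype[pos]
        ]

    @property
    def total_classified(self) -> int:
        return self.wildtype_count + sum(self.counts.values())


# ---------------------------------------------------------------------------
# FASTQ plumbing
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str]]:
    """Yield (read1, read2) sequence strings from paired FASTQ files."""
    with _open_maybe_gz(r1_path) as f1, _open_maybe_gz(r2_path) as f2:
        while True:
            h1 = f1.readline()
            h2 = f2.readline()
            if not h1 and not h2:
                return
            if not h1 or not h2:
                raise ValueError("paired FASTQ files have unequal lengths")
            s1 = f1.readline().strip()
            s2 = f2.readline().strip()
            plus1, plus2 = f1.readline(), f2.readline()
            q1, q2 = f1.readline().strip(), f2.readline().strip()
            if not plus1.startswith("+") or not plus2.startswith("+"):
                raise ValueError("malformed FASTQ record")
            if len(q1) != len(s1) or len(q2) != len(s2):
                raise ValueError("quality/sequence length mismatch")
            yield s1, s2


def extract_span(
    read_pair: tuple[str, str], construct: Construct
) -> str | Reject:
    """Reconstruct the scanned-span DNA from a read pair, or reject.

    Read 1 is the amplicon's forward strand from its 5' end; read 2 is the
    reverse strand from the 3' end. The two reads must together cover the
    whole amplicon; wherever both cover a base of the *span*, they must
    agree (disagreement means a sequencing error and the pair is dropped).
    Both constant flanks must match exactly.
    """
    r1, r2 = read_pair
    amplicon = construct.amplicon
    amp_len = len(amplicon)
    s2 = reverse_complement(r2)
    off2 = amp_len - len(s2)  # alignment offset of read 2 on the amplicon
    if len(r1) < amp_len and off2 > len(r1):
        return Reject("incomplete_coverage")

    span_off = construct.span_nt_offset_in_amplicon()
    span_len = 3 * construct.span_length
    merged = []
    for i in range(amp_len):
        b1 = r1[i] if i < len(r1) else None
        b2 = s2[i - off2] if i >= off2 else None
        if b1 is not None and b2 is not None and b1 != b2:
            if span_off <= i < span_off + span_len:
                return Reject("overlap_conflict")
            # conflicting constant-context base: the expected base is
            # known, so keep the read copy that matches it (single-read
            # sequencing errors outside the span are thereby corrected;
            # a true mismatch present in both copies still rejects below)
            merged.append(b1 if b1 == amplicon[i] else b2)
            continue
        merged.append(b1 if b1 is not None else b2)
    seq = "".join(merged)

    up, down = construct.upstream_flank, construct.downstream_flank
    if not seq.startswith(up) or not seq.endswith(down):
        return Reject("flank_mismatch")
    span = seq[span_off : span_off + span_len]
    if len(span) != span_len or len(span) % 3 != 0:
        return Reject("bad_frame")
    return span


def classify_variant(
    span_dna: str, construct: Construct
) -> VariantId | Reject:
    """Translate a span and call wild type / single mutant / reject."""
    if len(span_dna) != 3 * construct.span_length:
        return Reject("bad_frame")
    prot = translate(span_dna)
    if "*" in prot:
        return Reject("stop")
    wt = construct.span_protein
    diffs = [i for i, (a, b) in enumerate(zip(wt, prot)) if a != b]
    if not diffs:
        return VariantId(construct.span[0], wt[0], is_wildtype=True)
    if len(diffs) > 1:
        return Reject("multi_mutant")
    i = diffs[0]
    return VariantId(construct.span[0] + i, prot[i], is_wildtype=False)


def count_population(
    r1_path: str | Path,
    r2_path: str | Path,
    construct: Construct,
    population: str = "reference",
) -> CountTable:
    """Count variants over all read pairs of one population.

    Classification of identical read pairs is cached, which makes counting
    fast on amplicon data where a handful of sequences dominate.
    """
    counts: dict[tuple[int, str], int] = {}
    qc = {r: 0 for r in REJECT_REASONS}
    wt_count = 0
    total = 0
    passing = 0
    cache: dict[tuple[str, str], VariantId | Reject] = {}

    for pair in iter_fastq_pairs(r1_path, r2_path):
        total += 1
        res = cache.get(pair)
        if res is None:
            span = extract_span(pair, construct)
            res = span if isinstance(span, Reject) else classify_variant(
                span, construct
            )
            cache[pair] = res
        if isinstance(res, Reject):
            qc[res.reason] += 1
            continue
        passing += 1
        if res.is_wildtype:
            wt_count += 1
        else:
            key = (res.position, res.aa)
            counts[key] = counts.get(key, 0) + 1

    return CountTable(
        population=population,
        counts=counts,
        wildtype_count=wt_count,
        wildtype=construct.wildtype_map(),
        n_reads_total=total,
        n_reads_passing=passing,
        qc=qc,
    )


def apply_reference_filter(
    tables: Mapping[str, CountTable] | CountTable, min_count: int = 100
) -> frozenset[tuple[int, str]]:
    """Variants with reference counts below ``min_count``, to be masked.

    ``tables`` may be a single reference table or a mapping of population
    label -> table containing a ``"reference"`` entry. The returned mask
    applies to every population of the experiment.
    """
    if isinstance(tables, CountTable):
        reference = tables
    else:
        try:
            reference = tables["reference"]
        except KeyError:
            raise ValueError("no reference population supplied") from None
    return frozenset(
        v for v in reference.variant_universe
        if reference.counts.get(v, 0) < min_count
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_counts_tsv(table: CountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# population={table.population}\n")
        fh.write(f"# wildtype_count={table.wildtype_count}\n")
        fh.write(f"# n_reads_total={table.n_reads_total}\n")
        fh.write(f"# n_reads_passing={table.n_reads_passing}\n")
        if table.qc:
            fh.write(f"# qc={json.dumps(table.qc, sort_keys=True)}\n")
        fh.write("population\tposition\twt_aa\tmut_aa\tcount\n")
        for pos in sorted(table.wildtype):
            wt = table.wildtype[pos]
            for aa in AMINO_ACIDS:
                if aa == wt:
                    continue
                fh.write(
                    f"{table.population}\t{pos}\t{wt}\t{aa}\t"
                    f"{table.counts.get((pos, aa), 0)}\n"
                )


def read_counts_tsv(path: str | Path) -> CountTable:
    meta: dict[str, str] = {}
    counts: dict[tuple[int, str], int] = {}
    wildtype: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value
                continue
            if line.startswith("population\t") or not line:
                continue
            _pop, pos, wt, aa, count = line.split("\t")
            pos = int(pos)
            wildtype[pos] = wt
            if int(count):
                counts[(pos, aa)] = int(count)
    return CountTable(
        population=meta.get("population", "unknown"),
        counts=counts,
        wildtype_count=int(meta.get("wildtype_count", 0)),
        wildtype=wildtype,
        n_reads_total=int(meta.get("n_reads_total", 0)),
        n_reads_passing=int(meta.get("n_reads_passing", 0)),
        qc=json.loads(meta["qc"]) if "qc" in meta else {},
    )


def write_qc_json(table: CountTable, path: str | Path) -> None:
    report = {
        "population": table.population,
        "n_reads_total": table.n_reads_total,
        "n_reads_passing": table.n_reads_passing,
        "pass_fraction": (
            table.n_reads_passing / table.n_reads_total
            if table.n_reads_total else 0.0
        ),
        "rejections": table.qc,
        "wildtype_count": table.wildtype_count,
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
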