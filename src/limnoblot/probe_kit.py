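"""In-silico hybridization of oligonucleotide probes and primers.

Reverse line blot hybridization (RLBH) screens a labeled PCR amplicon against
a membrane of immobilized group-specific probes.  This module provides the
dry-lab counterpart: IUPAC-degenerate probe matching against ITS sequence
records on either strand, in-silico PCR (nested PCR by composition),
probe-set coverage statistics, and melting-temperature estimation.

Degeneracy semantics: a degenerate letter in the *probe* matches any base of
its IUPAC set; an ``N`` in the *target* matches nothing by default (it is
sequencing uncertainty, not designed degeneracy) unless ``target_n_matches``
is set.  Coordinates are 0-based half-open throughout; antisense hits are
reported at the sense-strand coordinate of the window start.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "IUPAC_SETS",
    "Probe",
    "PrimerPair",
    "ITSRecord",
    "ProbeHit",
    "Amplicon",
    "CoverageReport",
    "TmEstimate",
    "expand_iupac",
    "expand_sequence",
    "reverse_complement",
    "match_probe",
    "in_silico_pcr",
    "nested_pcr",
    "compute_coverage",
    "melting_temperature",
    "read_fasta",
    "write_fasta",
    "read_probe_table",
    "load_builtin_probes",
    "load_builtin_primer_pairs",
]

IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYMKSWBDHVN", "TGCAYRKMSWVHDBN")

# 4-bit base encoding: A=1, C=2, G=4, T=8; a degenerate letter is the OR of
# its set, so probe-vs-target compatibility is a single AND.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASK = {code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()}


def expand_iupac(code: str) -> frozenset[str]:
    """Return the canonical base set of a single IUPAC letter."""
    try:
        return IUPAC_SETS[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC nucleotide code: {code!r}") from None


def _validate_iupac(sequence: str, what: str) -> None:
    if not sequence:
        raise ValueError(f"{what}: sequence must be non-empty")
    bad = set(sequence) - IUPAC_SETS.keys()
    if bad:
        raise ValueError(f"{what}: invalid IUPAC letter(s) {sorted(bad)!r} in {sequence!r}")


def reverse_complement(sequence: str) -> str:
    """Reverse complement honouring degenerate letters (R<->Y, B<->V, ...)."""
    _validate_iupac(sequence, "reverse_complement")
    return sequence.translate(_COMPLEMENT)[::-1]


def expand_sequence(sequence: str, limit: int = 10_000) -> list[str]:
    """All concrete A/C/G/T expansions of a degenerate sequence.

    Raises if the expansion count would exceed ``limit`` (product of set
    sizes), which guards against pathological all-N input.
    """
    _validate_iupac(sequence, "expand_sequence")
    n = 1
    for letter in sequence:
        n *= len(IUPAC_SETS[letter])
        if n > limit:
            raise ValueError(f"sequence expands to more than {limit} concrete oligos")
    return ["".join(p) for p in itertools.product(*(sorted(IUPAC_SETS[c]) for c in sequence))]


@dataclass(frozen=True)
class Probe:
    """A named IUPAC oligonucleotide with an optional reported Tm (°C)."""

    name: str
    sequence: str
    tm_reported: float | None = None

    def __post_init__(self) -> None:
        _validate_iupac(self.sequence, f"probe {self.name!r}")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"probe {self.name!r}: sequence must be uppercase")
        if self.tm_reported is not None:
            if not np.isfinite(self.tm_reported) or not (40.0 <= self.tm_reported <= 80.0):
                raise ValueError(
                    f"probe {self.name!r}: reported Tm {self.tm_reported} outside 40-80 °C"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse PCR primer pair (both written 5'→3')."""

    forward: str
    reverse: str
    label: str = ""

    def __post_init__(self) -> None:
        _validate_iupac(self.forward, f"primer pair {self.label!r} forward")
        _validate_iupac(self.reverse, f"primer pair {self.label!r} reverse")


@dataclass(frozen=True)
class ITSRecord:
    """A 16S–23S ITS (or ITS-bearing) nucleotide sequence record."""

    id: str
    sequence: str
    group_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ITSRecord: id must be non-empty")
        if not self.sequence:
            raise ValueError(f"ITSRecord {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"ITSRecord {self.id!r}: invalid letters {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class ProbeHit:
    record_id: str
    position: int  # 0-based window start, sense-strand coordinates
    strand: Literal["sense", "antisense"]
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    record_id: str
    start: int
    end: int  # half-open on the sense strand
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_record(self, suffix: str = "amplicon") -> ITSRecord:
        return ITSRecord(id=f"{self.record_id}|{suffix}:{self.start}-{self.end}", sequence=self.sequence)


@dataclass
class CoverageReport:
    """Which records each probe hits, and panel-level coverage statistics."""

    per_probe_targets: dict[str, set[str]]
    n_records: int
    record_ids: list[str] = field(repr=False, default_factory=list)

    @property
    def covered_ids(self) -> set[str]:
        return set().union(*self.per_probe_targets.values()) if self.per_probe_targets else set()

    @property
    def fraction_covered(self) -> float:
        return len(self.covered_ids) / self.n_records

    @property
    def mean_targets_per_probe(self) -> float:
        return sum(len(v) for v in self.per_probe_targets.values()) / len(self.per_probe_targets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe": list(self.per_probe_targets),
                "n_targets": [len(v) for v in self.per_probe_targets.values()],
                "targets": [",".join(sorted(v)) for v in self.per_probe_targets.values()],
            }
        )


def _encode(seq: str, n_matches_all: bool) -> np.ndarray:
    table = np.zeros(128, dtype=np.uint8)
    for code, mask in _CODE_MASK.items():
        table[ord(code)] = mask
    table[ord("N")] = 15 if n_matches_all else 0
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan(probe_seq: str, target: str, max_mismatches: int, target_n_matches: bool) -> list[tuple[int, int]]:
    """(position, mismatches) for every window where probe binds the target."""
    m, n = len(probe_seq), len(target)
    if m > n:
        return []
    pmask = np.array([_CODE_MASK[c] for c in probe_seq], dtype=np.uint8)
    tmask = _encode(target, n_matches_all=target_n_matches)
    windows = np.lib.stride_tricks.sliding_window_view(tmask, m)
    mism = ((windows & pmask) == 0).sum(axis=1)
    pos = np.nonzero(mism <= max_mismatches)[0]
    return [(int(p), int(mism[p])) for p in pos]


def match_probe(
    probe: Probe,
    record: ITSRecord,
    max_mismatches: int = 0,
    strands: Literal["sense", "antisense", "both"] = "both",
    target_n_matches: bool = False,
) -> list[ProbeHit]:
    """Find every binding window of ``probe`` on ``record``.

    A window is a hit when the count of positions whose target base is not in
    the probe letter's IUPAC set is ``<= max_mismatches``.  Both strands are
    searched by default (denatured double-stranded amplicon can hybridize via
    either strand); an antisense hit is located where the reverse complement
    of the probe matches the sense strand, reported at the window start in
    sense-strand coordinates.  Hits are sorted by (position, strand) with
    sense before antisense.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if strands not in ("sense", "antisense", "both"):
        raise ValueError(f"invalid strand selection {strands!r}")
    hits: list[ProbeHit] = []
    if strands in ("sense", "both"):
        for pos, mm in _scan(probe.sequence, record.sequence, max_mismatches, target_n_matches):
            hits.append(ProbeHit(record.id, pos, "sense", mm))
    if strands in ("antisense", "both"):
        rc = reverse_complement(probe.sequence)
        for pos, mm in _scan(rc, record.sequence, max_mismatches, target_n_matches):
            hits.append(ProbeHit(record.id, pos, "antisense", mm))
    hits.sort(key=lambda h: (h.position, h.strand == "antisense"))
    return hits


def in_silico_pcr(
    pair: PrimerPair,
    record: ITSRecord,
    max_mismatches: int = 0,
    length_bounds: tuple[int, int] = (100, 5000),
) -> list[Amplicon]:
    """Enumerate amplicons of a primer pair on one template.

    The forward primer must bind the sense strand; the reverse primer binds
    the antisense strand, i.e. its reverse complement appears on the sense
    strand downstream.  The product runs from the forward binding-site start
    to the end of the reverse binding site (both inclusive of the primers).
    Nested PCR is expressed by composing two calls (see :func:`nested_pcr`).
    """
    lo, hi = length_bounds
    if lo < len(pair.forward) + len(pair.reverse):
        raise ValueError("length_bounds minimum must cover both primers")
    fwd = Probe(name="fwd", sequence=pair.forward)
    rev_site = Probe(name="rev_rc", sequence=reverse_complement(pair.reverse))
    fwd_hits = match_probe(fwd, record, max_mismatches, strands="sense")
    rev_hits = match_probe(rev_site, record, max_mismatches, strands="sense")
    out = []
    for f in fwd_hits:
        for r in rev_hits:
            end = r.position + len(pair.reverse)
            length = end - f.position
            if lo <= length <= hi:
                out.append(Amplicon(record.id, f.position, end, record.sequence[f.position:end]))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def nested_pcr(
    outer: PrimerPair,
    inner: PrimerPair,
    record: ITSRecord,
    max_mismatches: int = 0,
    outer_bounds: tuple[int, int] = (100, 5000),
    inner_bounds: tuple[int, int] = (100, 5000),
) -> list[Amplicon]:
    """Two-round PCR: the inner pair re-amplifies each outer product.

    Inner amplicon coordinates are mapped back onto the original record.
    """
    products = []
    for amp in in_silico_pcr(outer, record, max_mismatches, outer_bounds):
        for nested in in_silico_pcr(inner, amp.as_record(), max_mismatches, inner_bounds):
            products.append(
                Amplicon(record.id, amp.start + nested.start, amp.start + nested.end, nested.sequence)
            )
    products.sort(key=lambda a: (a.start, a.end))
    return products


def compute_coverage(
    probes: Sequence[Probe],
    records: Sequence[ITSRecord],
    max_mismatches: int = 0,
    target_n_matches: bool = False,
) -> CoverageReport:
    """Per-probe target sets and panel coverage across a record collection.

    A record counts as covered when at least one probe hits it on either
    strand.  ``fraction_covered`` is |union of target sets| / |records|;
    ``mean_targets_per_probe`` averages target-set sizes over probes.
    """
    if not probes:
        raise ValueError("compute_coverage: need at least one probe")
    if not records:
        raise ValueError("compute_coverage: need at least one record")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("compute_coverage: duplicate record ids")
    targets: dict[str, set[str]] = {}
    for probe in probes:
        targets[probe.name] = {
            r.id
            for r in records
            if len(probe) <= len(r)
            and match_probe(probe, r, max_mismatches, "both", target_n_matches)
        }
    return CoverageReport(per_probe_targets=targets, n_records=len(records), record_ids=ids)


@dataclass(frozen=True)
class TmEstimate:
    celsius: float
    method: str


def melting_temperature(
    sequence: str,
    method: Literal["wallace", "nearest-neighbor"] = "nearest-neighbor",
) -> TmEstimate:
    """Estimate an oligo melting temperature.

    ``wallace``: 2·(A+T) + 4·(G+C) °C; degenerate letters contribute the mean
    over their base set (equivalent to averaging over all expansions, since
    the rule is per-position additive).  ``nearest-neighbor``: SantaLucia
    (2004) parameters via Biopython's ``Tm_NN`` with its default buffer
    conditions; degenerate oligos are averaged over all concrete expansions.
    """
    _validate_iupac(sequence, "melting_temperature")
    if method == "wallace":
        tm = 0.0
        for letter in sequence:
            bases = IUPAC_SETS[letter]
            tm += sum(2.0 if b in "AT" else 4.0 for b in bases) / len(bases)
        return TmEstimate(tm, "wallace")
    if method == "nearest-neighbor":
        values = [_mt.Tm_NN(Seq(s)) for s in expand_sequence(sequence, limit=512)]
        return TmEstimate(float(np.mean(values)), "nearest-neighbor")
    raise ValueError(f"unknown Tm method {method!r}")


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path, group_labels: Mapping[str, str] | None = None) -> list[ITSRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = group_labels.get(rec.id) if group_labels else None
        records.append(ITSRecord(id=rec.id, sequence=str(rec.seq).upper(), group_label=label))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate record ids in {path}")
    return records


def write_fasta(records: Iterable[ITSRecord], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seq_records)


def read_probe_table(path: str | Path) -> list[Probe]:
    """Read probes from a TSV with columns ``name``, ``sequence``, ``tm``."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "sequence": str})
    missing = {"name", "sequence"} - set(df.columns)
    if missing:
        raise ValueError(f"probe table {path}: missing column(s) {sorted(missing)}")
    probes = []
    for row in df.itertuples(index=False):
        tm = getattr(row, "tm", None)
        tm = None if tm is None or pd.isna(tm) else float(tm)
        probes.append(Probe(name=row.name, sequence=row.sequence.strip().upper(), tm_reported=tm))
    return probes


def _resource(name: str):
    return resources.files("limnoblot.resources").joinpath(name)


def load_builtin_probes() -> list[Probe]:
    """The packaged 18-probe Limnohabitans ITS panel (names, sequences, Tm)."""
    with resources.as_file(_resource("probes.tsv")) as p:
        return read_probe_table(p)


def load_builtin_primer_pairs() -> dict[str, PrimerPair]:
    """Packaged primer pairs: genus-specific ITS pair and universal ITS pair."""
    with resources.as_file(_resource("primers.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return {
        row.label: PrimerPair(forward=row.forward, reverse=row.reverse, label=row.label)
        for row in df.itertuples(index=False)
    }
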