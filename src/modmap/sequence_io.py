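"""FASTA input/output, sequence cleaning, and synthetic sequence generation.

Sequences are held as :class:`SequenceRecord` objects whose residues are
strictly over the uppercase alphabet ``ACGT``.  Cleaning on read is
deterministic: lowercase is uppercased, ``U`` is mapped to ``T`` (so
RNA-alphabet files are accepted), and every other symbol (``N``, IUPAC
ambiguity codes, gaps, whitespace artefacts) is removed and counted in
``skipped_count``.

The module also provides two synthetic-sequence generators:

* :func:`shuffle_preserving_trinucleotides` — a uniform random Eulerian-path
  shuffle on the order-2 de Bruijn multigraph of a sequence.  The output has
  exactly the same length and the same overlapping trinucleotide counts as
  the input (exact preservation, not merely in expectation).
* :func:`simulate_markov_family` — families of sequences drawn from related
  Markov chains, used as an end-to-end test bed for the full
  CGR → DSSIM → MDS pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: All 64 trinucleotides in lexicographic order.
TRINUCLEOTIDES = ["".join(p) for p in itertools.product(ALPHABET, repeat=3)]


@dataclass(frozen=True)
class SequenceRecord:
    """A cleaned DNA sequence with provenance of removed symbols.

    Invariants: ``residues`` contains only uppercase A/C/G/T, and
    ``len(residues) + skipped_count == original_length``.
    """

    id: str
    residues: str
    description: str = ""
    original_length: int = -1
    skipped_count: int = 0

    def __post_init__(self) -> None:
        if self.original_length < 0:
            object.__setattr__(self, "original_length", len(self.residues))
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues contain non-ACGT symbols {sorted(bad)}"
            )
        if len(self.residues) + self.skipped_count != self.original_length:
            raise ValueError(
                f"record {self.id!r}: length {len(self.residues)} + skipped "
                f"{self.skipped_count} != original_length {self.original_length}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TrinucleotideProfile:
    """Overlapping 3-mer counts of a sequence (64 entries, lexicographic)."""

    counts: dict[str, int]
    source_length: int

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        expected = max(self.source_length - 2, 0)
        if total != expected:
            raise ValueError(
                f"trinucleotide counts sum to {total}, expected {expected}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.counts.get(w, 0) for w in TRINUCLEOTIDES])


def clean_residues(raw: str) -> tuple[str, int]:
    """Uppercase, map U->T, drop everything outside ACGT.

    Returns the cleaned string and the number of symbols removed.
    """
    up = raw.upper().replace("U", "T")
    kept = [c for c in up if c in _BASE_INDEX]
    return "".join(kept), len(up) - len(kept)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into cleaned :class:`SequenceRecord` objects.

    One record per FASTA entry, in file order.  Raises ``ValueError`` on an
    empty file, on duplicate ids, and on entries whose cleaned residues are
    empty.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        raw = str(entry.seq)
        residues, skipped = clean_residues(raw)
        if not residues:
            raise ValueError(f"entry {entry.id!r} has no A/C/G/T residues after cleaning")
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        records.append(
            SequenceRecord(
                id=entry.id,
                residues=residues,
                description=desc,
                original_length=len(raw),
                skipped_count=skipped,
            )
        )
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA with fixed-width line wrapping (default 70)."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated metadata table with columns id, name, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"id", "name", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in metadata: {dups}")
    return df


def encode(residues: str) -> np.ndarray:
    """Encode A/C/G/T as integers 0..3 (lexicographic)."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def trinucleotide_profile(record: SequenceRecord | str) -> TrinucleotideProfile:
    """Count overlapping occurrences of each of the 64 trinucleotides."""
    residues = record.residues if isinstance(record, SequenceRecord) else record
    if len(residues) < 3:
        raise ValueError("sequence too short for order-3 profile (need length >= 3)")
    codes = encode(residues)
    idx = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
    counts = np.bincount(idx, minlength=64)
    return TrinucleotideProfile(
        counts={w: int(c) for w, c in zip(TRINUCLEOTIDES, counts)},
        source_length=len(residues),
    )


def _last_exit_arborescence(
    adjacency: dict[str, list[str]], end: str, rng: np.random.Generator
) -> dict[str, str]:
    """Sample a uniform random last-exit arborescence into ``end``.

    For every node with out-edges (except ``end``) pick a successor uniformly
    over its out-edge multiset; accept iff following those picks from every
    node reaches ``end`` without cycling.  Conditioned on acceptance the
    arborescence is uniform (multiplicity-weighted), which together with a
    uniform permutation of the remaining out-edges yields a uniform random
    Eulerian path.  Rejection terminates with probability 1 because ``end``
    is reachable from every node of the walk's multigraph.
    """
    nodes = [u for u in adjacency if u != end and adjacency[u]]
    while True:
        last = {u: adjacency[u][rng.integers(len(adjacency[u]))] for u in nodes}
        ok = True
        for u in nodes:
            seen = {u}
            v = u
            while v != end:
                v = last.get(v)
                if v is None or v in seen:
                    ok = False
                    break
                seen.add(v)
            if not ok:
                break
        if ok:
            return last


def shuffle_preserving_trinucleotides(
    record: SequenceRecord, seed: int = 0
) -> SequenceRecord:
    """Randomize a sequence while exactly preserving its trinucleotide counts.

    The sequence is viewed as an Eulerian path on the order-2 de Bruijn
    multigraph (nodes = dinucleotides, one edge per overlapping
    trinucleotide occurrence).  A uniform random Eulerian path with the same
    start node (the input's first dinucleotide) is drawn, which preserves
    length, all 3-mer counts (hence all 2-mer and 1-mer counts), and is
    deterministic for a given ``seed``.
    """
    s = record.residues
    if len(s) < 3:
        raise ValueError("sequence too short for order-3 profile (need length >= 3)")
    rng = np.random.default_rng(seed)

    adjacency: dict[str, list[str]] = {}
    for i in range(len(s) - 2):
        adjacency.setdefault(s[i : i + 2], []).append(s[i + 1 : i + 3])
    start, end = s[:2], s[-2:]

    last = _last_exit_arborescence(adjacency, end, rng)

    # Shuffle each out-edge list; park one copy of the arborescence edge last.
    ready: dict[str, list[str]] = {}
    for u, succ in adjacency.items():
        succ = list(succ)
        if u in last:
            succ.remove(last[u])
        order = rng.permutation(len(succ))
        shuffled = [succ[j] for j in order]
        if u in last:
            shuffled.append(last[u])
        ready[u] = shuffled[::-1]  # pop() from the end = consume in order

    out = [start]
    node = start
    total_edges = len(s) - 2
    for _ in range(total_edges):
        node = ready[node].pop()
        out.append(node[1])
    shuffled_seq = "".join(out)
    assert len(shuffled_seq) == len(s)
    return SequenceRecord(
        id=f"{record.id}_shuffle{seed}",
        residues=shuffled_seq,
        description=f"trinucleotide-preserving shuffle (seed={seed}) of {record.id}",
    )


def simulate_markov_family(
    family_count: int,
    per_family: int,
    length: int,
    order: int = 2,
    divergence: float = 0.5,
    seed: int = 0,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate families of sequences from related Markov chains.

    A shared base transition table (rows Dirichlet(1)) is perturbed per
    family: each family row is ``(1 - divergence) * base + divergence * own``
    with ``own`` an independent Dirichlet(1) draw, so ``divergence`` in [0, 1]
    interpolates between identical generative laws (0) and independent ones
    (1).  Returns the records and a metadata table (id, name, group).

    Deterministic given ``seed``.
    """
    if family_count < 1 or per_family < 1 or length < 1:
        raise ValueError("family_count, per_family and length must be positive")
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_states = 4**order
    base = rng.dirichlet(np.ones(4), size=n_states)

    records: list[SequenceRecord] = []
    meta_rows = []
    for f in range(family_count):
        own = rng.dirichlet(np.ones(4), size=n_states)
        table = (1.0 - divergence) * base + divergence * own
        table /= table.sum(axis=1, keepdims=True)
        cum = np.cumsum(table, axis=1)
        for j in range(per_family):
            u = rng.random(length)
            seq = np.empty(length, dtype=np.int64)
            state = 0  # implicit all-A initial context
            for pos in range(length):
                b = int(np.searchsorted(cum[state], u[pos], side="right"))
                b = min(b, 3)
                seq[pos] = b
                if order > 0:
                    state = (state * 4 + b) % n_states
            residues = "".join(ALPHABET[b] for b in seq)
            rec_id = f"fam{f}_seq{j}"
            records.append(
                SequenceRecord(
                    id=rec_id,
                    residues=residues,
                    description=f"Markov order-{order} family {f}",
                )
            )
            meta_rows.append({"id": rec_id, "name": rec_id, "group": f"family{f}"})
    metadata = pd.DataFrame(meta_rows, columns=["id", "name", "group"])
    return records, metadata
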