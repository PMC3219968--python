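"""Genome length tables and whole-genome match coordinates.

The synteny classification pipeline consumes two inputs per genome pair:
the ordered sequence lengths of each assembly (contigs, scaffolds or
chromosomes) and the coordinates of translated-DNA matches between them,
as produced by MUMmer's ``promer`` / ``delta-filter`` / ``show-coords``
tool chain.  This module reads both, applies the minimum-sequence-length
filter (sequences shorter than 500 kb are discarded before any
statistics are computed), and defines the in-memory model that every
downstream module consumes.

Conventions
-----------
* Coordinates are 1-based and inclusive throughout, matching MUMmer;
  the length of an interval is ``end - start + 1``.
* A :class:`Match` is stored with ascending coordinates on both axes;
  a raw row whose query interval descends is recorded as
  ``antiparallel``.
* Orientation is carried for dot-plot colouring only; the classifier
  itself never consults it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Minimum sequence length retained by default, in bp.
DEFAULT_MIN_SEQ_LEN = 500_000

#: Orientation labels for a match.
PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"

_MATCHSET_MAGIC = "#mesoscan-matchset"
_MATCHSET_VERSION = "v1"


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered sequence identifiers with lengths for one assembly.

    Parameters
    ----------
    label:
        A free-text name for the assembly (species, strain, file stem).
    sequences:
        Ordered ``(seq_id, length)`` pairs.  The order is preserved as
        given because it defines the dot-plot axis layout.
    """

    label: str
    sequences: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seq_id, length in self.sequences:
            if seq_id in seen:
                raise ValueError(f"duplicate sequence id {seq_id!r} in genome {self.label!r}")
            seen.add(seq_id)
            if length <= 0:
                raise ValueError(
                    f"non-positive length {length} for sequence {seq_id!r} in genome {self.label!r}"
                )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(seq_id for seq_id, _ in self.sequences)

    @property
    def lengths(self) -> Mapping[str, int]:
        return dict(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, seq_id: str) -> bool:
        return any(seq_id == s for s, _ in self.sequences)

    def length_of(self, seq_id: str) -> int:
        for s, length in self.sequences:
            if s == seq_id:
                return length
        raise KeyError(seq_id)


@dataclass(frozen=True)
class Match:
    """One homologous segment between a reference and a query sequence.

    Coordinates are 1-based inclusive and ascending on both axes after
    normalization; ``orientation`` records whether the raw query
    interval descended (``antiparallel``).
    """

    ref_id: str
    qry_id: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    pct_similarity: float
    orientation: str = PARALLEL

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end or self.qry_start > self.qry_end:
            raise ValueError("match coordinates must be normalized (start <= end)")
        if self.ref_start < 1 or self.qry_start < 1:
            raise ValueError("match coordinates are 1-based; start must be >= 1")
        if not 0.0 <= self.pct_similarity <= 100.0:
            raise ValueError(f"pct_similarity {self.pct_similarity} outside [0, 100]")
        if self.orientation not in (PARALLEL, ANTIPARALLEL):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def ref_span(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)

    @property
    def qry_span(self) -> tuple[int, int]:
        return (self.qry_start, self.qry_end)


@dataclass(frozen=True)
class MatchSet:
    """All matches between two (length-filtered) genomes."""

    genome_a: GenomeIndex
    genome_b: GenomeIndex
    matches: tuple[Match, ...]

    def __post_init__(self) -> None:
        len_a = self.genome_a.lengths
        len_b = self.genome_b.lengths
        for m in self.matches:
            if m.ref_id not in len_a:
                raise ValueError(f"match references unknown sequence {m.ref_id!r} in genome A")
            if m.qry_id not in len_b:
                raise ValueError(f"match references unknown sequence {m.qry_id!r} in genome B")
            if m.ref_end > len_a[m.ref_id] or m.qry_end > len_b[m.qry_id]:
                raise ValueError(
                    f"match {m.ref_id}:{m.ref_start}-{m.ref_end} / "
                    f"{m.qry_id}:{m.qry_start}-{m.qry_end} exceeds sequence bounds"
                )

    def by_pair(self) -> dict[tuple[str, str], list[Match]]:
        """Group matches by ``(ref_id, qry_id)`` sequence pair."""
        groups: dict[tuple[str, str], list[Match]] = {}
        for m in self.matches:
            groups.setdefault((m.ref_id, m.qry_id), []).append(m)
        return groups

    def swapped(self) -> "MatchSet":
        """The same comparison with genomes A and B exchanged."""
        swapped = tuple(
            Match(
                ref_id=m.qry_id,
                qry_id=m.ref_id,
                ref_start=m.qry_start,
                ref_end=m.qry_end,
                qry_start=m.ref_start,
                qry_end=m.ref_end,
                pct_similarity=m.pct_similarity,
                orientation=m.orientation,
            )
            for m in self.matches
        )
        return MatchSet(self.genome_b, self.genome_a, swapped)


# ---------------------------------------------------------------------------
# genome length tables


def _looks_like_fasta(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.lstrip().startswith(">")
    return False


def _read_fasta_lengths(path: Path) -> Iterator[tuple[str, int]]:
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, len(record.seq)


def _read_table_lengths(path: Path) -> Iterator[tuple[str, int]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns (id, length)")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: length {fields[1]!r} is not an integer") from exc
            yield fields[0], length


def read_genome_index(path: str | Path, label: str | None = None) -> GenomeIndex:
    """Read sequence lengths from a FASTA file or a two-column table.

    FASTA input is detected by a leading ``>``; lengths are counted from
    the sequences.  Otherwise the file is parsed as tab- (or
    whitespace-) separated ``id<TAB>length`` rows, as in the first two
    columns of a ``samtools faidx`` index.

    Raises
    ------
    ValueError
        On duplicate sequence ids, non-positive lengths, or an empty
        file ("no sequences").
    """
    path = Path(path)
    if label is None:
        label = path.stem
    reader = _read_fasta_lengths if _looks_like_fasta(path) else _read_table_lengths
    sequences = tuple(reader(path))
    if not sequences:
        raise ValueError(f"no sequences in {path}")
    return GenomeIndex(label=label, sequences=sequences)


def filter_min_length(genome: GenomeIndex, min_len: int = DEFAULT_MIN_SEQ_LEN) -> GenomeIndex:
    """Discard sequences shorter than ``min_len`` (default 500 kb).

    A sequence of exactly ``min_len`` bp is retained.  The original
    order is preserved.  Filtering is idempotent.

    Raises
    ------
    ValueError
        If no sequence survives ("genome empty after filter"):
        classification is impossible without retained sequences.
    """
    retained = tuple((s, l) for s, l in genome.sequences if l >= min_len)
    if not retained:
        raise ValueError(
            f"genome {genome.label!r} empty after filter (min_len={min_len})"
        )
    return GenomeIndex(label=genome.label, sequences=retained)


# ---------------------------------------------------------------------------
# show-coords parsing


def _coords_tokens(line: str) -> list[str]:
    # Human-readable show-coords separates column groups with '|';
    # the tab dialect (-T) has none.  Either way, strip and split.
    return line.replace("|", " ").split()


def read_coords(
    path: str | Path,
    genome_a: GenomeIndex,
    genome_b: GenomeIndex,
    *,
    dropped_a: frozenset[str] | set[str] = frozenset(),
    dropped_b: frozenset[str] | set[str] = frozenset(),
) -> MatchSet:
    """Parse MUMmer ``show-coords`` output into a :class:`MatchSet`.

    Both the headerless tab dialect (``show-coords -T -H``) and the
    default human-readable layout are accepted; the dialect is detected
    per row.  ``promer`` rows carry three percentage columns
    (%IDY, %SIM, %STP) and ``pct_similarity`` maps to %SIM; ``nucmer``
    rows carry only %IDY, which is used instead.

    ``genome_a`` / ``genome_b`` are the **retained** (length-filtered)
    indexes.  Rows that name a sequence listed in ``dropped_a`` /
    ``dropped_b`` (discarded by the length filter) are skipped with a
    logged count; rows naming a sequence unknown to either set raise.

    Raises
    ------
    ValueError
        On a malformed row (with its line number) or an unknown
        sequence id.
    """
    path = Path(path)
    len_a = genome_a.lengths
    len_b = genome_b.lengths
    matches: list[Match] = []
    n_skipped = 0
    seen_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = _coords_tokens(line)
            # Header block of the human-readable format: file paths,
            # NUCMER/PROMER tag, column captions, '=====' rule.
            if not tokens or not _is_int(tokens[0]):
                if seen_data:
                    raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
                continue
            if len(tokens) < 9:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 9 fields, got {len(tokens)}"
                )
            ref_id, qry_id = tokens[-2], tokens[-1]
            numeric = tokens[:-2]
            try:
                s1, e1, s2, e2 = (int(v) for v in numeric[:4])
                # numeric[4:6] are LEN1/LEN2; percentage columns follow.
                n_pct = len(numeric) - 6
                if n_pct >= 2:
                    pct = float(numeric[7])  # %SIM (promer)
                elif n_pct == 1:
                    pct = float(numeric[6])  # %IDY (nucmer)
                else:
                    raise ValueError("missing percentage columns")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
            seen_data = True

            in_dropped = ref_id in dropped_a or qry_id in dropped_b
            if in_dropped:
                n_skipped += 1
                continue
            if ref_id not in len_a:
                raise ValueError(f"{path}:{lineno}: unknown reference sequence id {ref_id!r}")
            if qry_id not in len_b:
                raise ValueError(f"{path}:{lineno}: unknown query sequence id {qry_id!r}")

            ref_asc = s1 <= e1
            qry_asc = s2 <= e2
            orientation = PARALLEL if ref_asc == qry_asc else ANTIPARALLEL
            rs, re_ = (s1, e1) if ref_asc else (e1, s1)
            qs, qe = (s2, e2) if qry_asc else (e2, s2)
            if re_ > len_a[ref_id] or qe > len_b[qry_id]:
                raise ValueError(
                    f"{path}:{lineno}: match exceeds sequence bounds "
                    f"({ref_id}:{rs}-{re_}, {qry_id}:{qs}-{qe})"
                )
            matches.append(
                Match(ref_id, qry_id, rs, re_, qs, qe, pct, orientation)
            )
    if n_skipped:
        logger.info(
            "%s: skipped %d matches touching length-filtered sequences", path, n_skipped
        )
    return MatchSet(genome_a, genome_b, tuple(matches))


def _is_int(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


def load_comparison(
    coords_path: str | Path,
    genome_a: str | Path | GenomeIndex,
    genome_b: str | Path | GenomeIndex,
    min_len: int = DEFAULT_MIN_SEQ_LEN,
) -> MatchSet:
    """One-call pipeline front door: read, filter, and parse coordinates.

    ``genome_a`` / ``genome_b`` may be paths (FASTA or length table) or
    already-built :class:`GenomeIndex` objects.  Both are filtered at
    ``min_len`` and matches touching discarded sequences are dropped.
    """
    if not isinstance(genome_a, GenomeIndex):
        genome_a = read_genome_index(genome_a)
    if not isinstance(genome_b, GenomeIndex):
        genome_b = read_genome_index(genome_b)
    filtered_a = filter_min_length(genome_a, min_len)
    filtered_b = filter_min_length(genome_b, min_len)
    dropped_a = frozenset(genome_a.ids) - frozenset(filtered_a.ids)
    dropped_b = frozenset(genome_b.ids) - frozenset(filtered_b.ids)
    return read_coords(
        coords_path, filtered_a, filtered_b, dropped_a=dropped_a, dropped_b=dropped_b
    )


def filter_matchset(matchset: MatchSet, min_len: int = DEFAULT_MIN_SEQ_LEN) -> MatchSet:
    """Apply the minimum-length filter to an in-memory match set.

    Sequences shorter than ``min_len`` are discarded from both genome
    indexes and matches touching them are dropped.  Idempotent.
    """
    filtered_a = filter_min_length(matchset.genome_a, min_len)
    filtered_b = filter_min_length(matchset.genome_b, min_len)
    ids_a = frozenset(filtered_a.ids)
    ids_b = frozenset(filtered_b.ids)
    kept = tuple(
        m for m in matchset.matches if m.ref_id in ids_a and m.qry_id in ids_b
    )
    n_dropped = len(matchset.matches) - len(kept)
    if n_dropped:
        logger.info("dropped %d matches touching length-filtered sequences", n_dropped)
    return MatchSet(filtered_a, filtered_b, kept)


# ---------------------------------------------------------------------------
# matchset round-trip format


def write_matchset(matchset: MatchSet, path: str | Path) -> None:
    """Write a :class:`MatchSet` as a self-contained tab-separated file.

    The format is text-only and lossless: genome labels, sequence order
    and lengths, and every match field round-trip exactly.  Floats are
    written with ``repr`` so they re-read bit-identically.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_MATCHSET_MAGIC} {_MATCHSET_VERSION}\n")
        for tag, genome in (("A", matchset.genome_a), ("B", matchset.genome_b)):
            fh.write(f"#genome\t{tag}\t{genome.label}\n")
            for seq_id, length in genome.sequences:
                fh.write(f"#sequence\t{tag}\t{seq_id}\t{length}\n")
        fh.write(
            "#fields\tref_id\tqry_id\tref_start\tref_end\tqry_start\tqry_end"
            "\tpct_similarity\torientation\n"
        )
        for m in matchset.matches:
            fh.write(
                f"{m.ref_id}\t{m.qry_id}\t{m.ref_start}\t{m.ref_end}"
                f"\t{m.qry_start}\t{m.qry_end}\t{m.pct_similarity!r}\t{m.orientation}\n"
            )


def read_matchset(path: str | Path) -> MatchSet:
    """Read a file written by :func:`write_matchset`.

    Raises
    ------
    ValueError
        On a version/magic mismatch or malformed content.
    """
    path = Path(path)
    labels = {"A": "A", "B": "B"}
    sequences: dict[str, list[tuple[str, int]]] = {"A": [], "B": []}
    matches: list[Match] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"{_MATCHSET_MAGIC} {_MATCHSET_VERSION}":
            raise ValueError(
                f"{path}: not a mesoscan matchset v1 file (header {header!r})"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = line.split("\t")
                if fields[0] == "#genome":
                    labels[fields[1]] = fields[2]
                elif fields[0] == "#sequence":
                    sequences[fields[1]].append((fields[2], int(fields[3])))
                elif fields[0] == "#fields":
                    pass
                else:
                    raise ValueError(f"{path}:{lineno}: unknown directive {fields[0]!r}")
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 fields, got {len(fields)}")
            matches.append(
                Match(
                    ref_id=fields[0],
                    qry_id=fields[1],
                    ref_start=int(fields[2]),
                    ref_end=int(fields[3]),
                    qry_start=int(fields[4]),
                    qry_end=int(fields[5]),
                    pct_similarity=float(fields[6]),
                    orientation=fields[7],
                )
            )
    genome_a = GenomeIndex(labels["A"], tuple(sequences["A"]))
    genome_b = GenomeIndex(labels["B"], tuple(sequences["B"]))
    return MatchSet(genome_a, genome_b, tuple(matches))
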