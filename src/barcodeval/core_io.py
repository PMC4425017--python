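"""Species-labeled alignments: reading, writing, validation, and summary statistics.

The universal input of the toolkit is a pre-aligned FASTA file whose headers
carry both a species label and a sample identifier, by default in the form
``>Genus_species|sample_id``. Records are tied to a *region* tag (e.g. ITS1,
ITS2, ITS1+2) identifying the barcode locus the alignment covers.

Sequence characteristics computed here — counts of individuals, species and
singletons, alignment length, percentages of variable and parsimony-informative
sites, and the overall mean K2P distance — are the standard per-dataset
descriptors used when comparing candidate barcode loci.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import (
    AlignmentError,
    HeaderParseError,
    PairingError,
    ValidationError,
)

#: Default header convention: species and sample id separated by a pipe.
DEFAULT_HEADER_PATTERN = r"^(?P<species>[^|]+)\|(?P<sample>[^|]+)$"

# Unambiguous bases get codes 0..3; everything else (gaps, N, IUPAC
# ambiguities) is MISSING and excluded from site classification and
# distance computation (pairwise-deletion convention).
MISSING = np.uint8(255)
_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
_AMBIGUITY = set("RYSWKMBDHVN")
_ALPHABET = set("ACGT-") | _AMBIGUITY


def _normalize_residues(raw: str) -> str:
    """Upper-case, map U->T and '.' gaps to '-', and validate the alphabet."""
    s = raw.upper().replace("U", "T").replace(".", "-")
    bad = set(s) - _ALPHABET
    if bad:
        raise AlignmentError(f"invalid residue characters {sorted(bad)!r}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence tied to a species label and a sample identifier."""

    sample_id: str
    species: str
    residues: str
    region: str = ""

    def __post_init__(self):
        if not self.species:
            raise ValidationError("species label must be non-empty")
        if not self.residues:
            raise AlignmentError(f"record {self.sample_id!r}: empty residue string")
        object.__setattr__(self, "residues", _normalize_residues(self.residues))

    @property
    def label(self) -> str:
        """The canonical FASTA/newick label ``species|sample_id``."""
        return f"{self.species}|{self.sample_id}"


@dataclass
class LabeledAlignment:
    """An ordered collection of equal-length :class:`SequenceRecord`.

    Equal residue lengths and uniqueness of ``(species, sample_id)`` pairs
    are enforced at construction. Single-record alignments are accepted so
    that per-region fragments can be concatenated before analysis; every
    pairwise analysis additionally requires at least two records.
    """

    records: list[SequenceRecord]
    region: str = ""
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.records:
            raise ValidationError("alignment must contain at least one record")
        length = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != length:
                raise AlignmentError(
                    f"record {rec.label!r} has length {len(rec.residues)}, "
                    f"expected {length}"
                )
        keys = [(r.species, r.sample_id) for r in self.records]
        if len(set(keys)) != len(keys):
            seen, dups = set(), set()
            for k in keys:
                (dups if k in seen else seen).add(k)
            raise ValidationError(f"duplicate (species, sample_id) pairs: {sorted(dups)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].residues)

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def codes(self) -> np.ndarray:
        """(n_records, alignment_length) uint8 matrix; 0..3 = ACGT, 255 = missing."""
        if self._codes is None:
            lut = np.full(256, MISSING, dtype=np.uint8)
            for base, code in _BASE_CODES.items():
                lut[ord(base)] = code
            rows = [
                lut[np.frombuffer(r.residues.encode("ascii"), dtype=np.uint8)]
                for r in self.records
            ]
            self._codes = np.vstack(rows)
        return self._codes


@dataclass(frozen=True)
class AlignmentStats:
    """Per-dataset sequence characteristics of a candidate barcode alignment."""

    n_individuals: int
    n_species: int
    n_singletons: int
    alignment_length: int
    variable_pct: float
    pi_pct: float
    overall_k2p_pct: float

    def __post_init__(self):
        if not (self.n_singletons <= self.n_species <= self.n_individuals):
            raise ValidationError("require n_singletons <= n_species <= n_individuals")
        if not (0.0 <= self.pi_pct <= self.variable_pct <= 100.0):
            raise ValidationError("require 0 <= pi_pct <= variable_pct <= 100")


def read_labeled_fasta(
    path: str | Path,
    header_pattern: str = DEFAULT_HEADER_PATTERN,
    region: str = "",
) -> LabeledAlignment:
    """Read a species-labeled FASTA alignment.

    Parameters
    ----------
    path:
        FASTA file, wrapped or unwrapped.
    header_pattern:
        Regex with named groups ``species`` and ``sample`` applied to the full
        description line (without the ``>``). The default expects
        ``Genus_species|sample_id``; real GenBank headers can be accommodated
        by overriding it.
    region:
        Dataset tag stored on the alignment (e.g. ``ITS1``).

    Raises
    ------
    HeaderParseError
        A description does not match ``header_pattern`` (reports line number).
    AlignmentError
        Unequal sequence lengths or invalid residues.
    ValidationError
        Duplicate ``(species, sample_id)`` pairs.
    """
    path = Path(path)
    pattern = re.compile(header_pattern)
    text = path.read_text()
    header_lines = [i + 1 for i, ln in enumerate(text.splitlines()) if ln.startswith(">")]

    records = []
    for idx, rec in enumerate(SeqIO.parse(path, "fasta")):
        m = pattern.match(rec.description)
        if not m:
            line = header_lines[idx] if idx < len(header_lines) else None
            raise HeaderParseError(
                f"header {rec.description!r} does not match pattern "
                f"{header_pattern!r}",
                line=line,
            )
        try:
            records.append(
                SequenceRecord(
                    sample_id=m.group("sample"),
                    species=m.group("species"),
                    residues=str(rec.seq),
                    region=region,
                )
            )
        except AlignmentError as exc:
            raise AlignmentError(f"record {rec.description!r}: {exc}") from exc
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return LabeledAlignment(records=records, region=region)


def write_labeled_fasta(aln: LabeledAlignment, path: str | Path, wrap: int = 60) -> None:
    """Write an alignment with ``species|sample_id`` headers, order preserved."""
    with open(path, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.label}\n")
            seq = rec.residues
            if wrap:
                for start in range(0, len(seq), wrap):
                    fh.write(seq[start : start + wrap] + "\n")
            else:
                fh.write(seq + "\n")


def concatenate_regions(
    a: LabeledAlignment, b: LabeledAlignment, region: str | None = None
) -> LabeledAlignment:
    """Concatenate two region alignments sample-by-sample (e.g. ITS1 + ITS2).

    Every ``(species, sample_id)`` in one alignment must have exactly one
    partner in the other; residues are joined a-then-b and the combined
    region tag defaults to ``"{a.region}+{b.region}"``.
    """
    index_b = {(r.species, r.sample_id): r for r in b.records}
    missing_in_b = [k for r in a.records if (k := (r.species, r.sample_id)) not in index_b]
    keys_a = {(r.species, r.sample_id) for r in a.records}
    missing_in_a = [k for k in index_b if k not in keys_a]
    if missing_in_b or missing_in_a:
        parts = []
        if missing_in_b:
            parts.append(f"samples missing from second alignment: {sorted(missing_in_b)}")
        if missing_in_a:
            parts.append(f"samples missing from first alignment: {sorted(missing_in_a)}")
        raise PairingError("; ".join(parts))

    if region is None:
        region = f"{a.region}+{b.region}" if a.region and b.region else (a.region or b.region)
    joined = [
        SequenceRecord(
            sample_id=r.sample_id,
            species=r.species,
            residues=r.residues + index_b[(r.species, r.sample_id)].residues,
            region=region,
        )
        for r in a.records
    ]
    return LabeledAlignment(records=joined, region=region)


def _site_classification(codes: np.ndarray) -> tuple[int, int]:
    """Return (n_variable, n_parsimony_informative) over alignment columns.

    A variable site has >= 2 distinct unambiguous states; a
    parsimony-informative site has >= 2 states each present in >= 2 records.
    Gaps and ambiguities are ignored.
    """
    n_var = 0
    n_pi = 0
    for col in codes.T:
        states, counts = np.unique(col[col != MISSING], return_counts=True)
        if len(states) >= 2:
            n_var += 1
            if np.sum(counts >= 2) >= 2:
                n_pi += 1
    return n_var, n_pi


def alignment_stats(aln: LabeledAlignment, dist) -> AlignmentStats:
    """Compute the per-dataset characteristics table row.

    ``dist`` is the :class:`~barcodeval.distances.DistanceMatrix` computed
    from ``aln``; the overall K2P is the unweighted (pooled) mean of all
    defined off-diagonal pairwise distances, expressed in percent.
    """
    species_counts: dict[str, int] = {}
    for r in aln.records:
        species_counts[r.species] = species_counts.get(r.species, 0) + 1

    n_var, n_pi = _site_classification(aln.codes())
    length = aln.alignment_length

    iu = np.triu_indices(len(aln), k=1)
    defined = dist.defined[iu]
    vals = dist.values[iu][defined]
    overall = float(np.mean(vals)) * 100.0 if vals.size else float("nan")

    return AlignmentStats(
        n_individuals=len(aln),
        n_species=len(species_counts),
        n_singletons=sum(1 for c in species_counts.values() if c == 1),
        alignment_length=length,
        variable_pct=100.0 * n_var / length,
        pi_pct=100.0 * n_pi / length,
        overall_k2p_pct=overall,
    )


def stats_table(rows: Iterable[tuple[str, AlignmentStats]]) -> pd.DataFrame:
    """Tabulate (dataset, stats) pairs with the standard column set."""
    data = [
        {
            "dataset": name,
            "n_individuals": s.n_individuals,
            "n_species": s.n_species,
            "n_singletons": s.n_singletons,
            "alignment_length_bp": s.alignment_length,
            "variable_pct": round(s.variable_pct, 2),
            "pi_pct": round(s.pi_pct, 2),
            "overall_k2p_pct": round(s.overall_k2p_pct, 2),
        }
        for name, s in rows
    ]
    return pd.DataFrame(data)
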