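"""Sequence and count-matrix I/O.

Mature miRNAs are read from a miRBase-style ``mature.fa`` (RNA alphabet;
T is accepted on input and normalized to U).  Count matrices are
species-by-library TSV files with an optional sidecar metadata file
(YAML or JSON) mapping each library name to its condition / replicate /
sample labels, so that round trips are bit-exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
MIN_MIRNA_LEN = 15

CONDITIONS = ("unblocked", "blocked")


class FormatError(ValueError):
    """A file violated the expected FASTA/TSV contract."""


def normalize_rna(sequence: str) -> str:
    """Uppercase and map T->U.  Idempotent."""
    return sequence.strip().upper().replace("T", "U")


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence, 5'->3', RNA alphabet.

    ``isoform_offsets`` lists 5'-end variants as (offset, weight) pairs:
    a positive offset is a 5'-trimmed isomiR, a negative offset a
    5'-extended one.  Weights are fractions of the species' reads; any
    remainder is the canonical form.
    """

    name: str
    sequence: str
    precursor: str | None = None
    isoform_offsets: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) < MIN_MIRNA_LEN:
            raise ValueError(
                f"{self.name!r}: sequence length {len(seq)} < {MIN_MIRNA_LEN}; "
                "too short to be a mature miRNA"
            )
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.name!r}: non-RNA characters {sorted(bad)}")
        wsum = sum(w for _, w in self.isoform_offsets)
        if any(w < 0 for _, w in self.isoform_offsets) or wsum > 1 + 1e-9:
            raise ValueError(
                f"{self.name!r}: isoform weights must be non-negative and sum to <= 1 "
                f"(got sum {wsum})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_mature_fasta(
    path: str | Path, species_prefix: str | None = None
) -> list[MatureMiRNA]:
    """Read a miRBase-style mature FASTA.

    Only the first whitespace-separated header token is used as the
    identifier.  Records shorter than 15 nt are rejected with a warning;
    duplicate names raise :class:`FormatError`.
    """
    path = Path(path)
    records: list[MatureMiRNA] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if species_prefix is not None and not name.startswith(species_prefix):
            continue
        seen[name] = seen.get(name, 0) + 1
        try:
            records.append(MatureMiRNA(name=name, sequence=str(rec.seq)))
        except ValueError as exc:
            if "too short" in str(exc):
                logger.warning("skipping short record %s: %s", name, exc)
                seen[name] -= 1
            else:
                raise FormatError(f"malformed record {name!r}: {exc}") from exc
    dupes = sorted(n for n, c in seen.items() if c > 1)
    if dupes:
        raise FormatError(f"duplicate miRNA names: {dupes}")
    if not records:
        logger.warning("no mature miRNA records read from %s", path)
    return records


@dataclass(frozen=True)
class LibraryMeta:
    condition: str = "unblocked"
    replicate: str = "1"
    sample: str = ""

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


@dataclass
class CountMatrix:
    """Non-negative integer counts of species x libraries.

    Backed by a pandas DataFrame (index = species, columns = libraries)
    plus per-library metadata.
    """

    counts: pd.DataFrame
    metadata: dict[str, LibraryMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise FormatError(f"duplicate species names: {dupes}")
        if df.columns.has_duplicates:
            dupes = sorted(df.columns[df.columns.duplicated()].unique())
            raise FormatError(f"duplicate library names: {dupes}")
        arr = df.to_numpy()
        if arr.size and not pd.api.types.is_integer_dtype(df.dtypes.iloc[0]):
            raise FormatError("counts must be integral")
        if arr.size and (arr < 0).any():
            r, c = divmod(int((arr < 0).argmax()), arr.shape[1])
            raise FormatError(
                f"negative count at species {df.index[r]!r}, library {df.columns[c]!r}"
            )
        self.counts = df.astype("int64") if arr.size else df
        for lib in df.columns:
            self.metadata.setdefault(str(lib), LibraryMeta(sample=str(lib)))

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.counts.index]

    @property
    def libraries(self) -> list[str]:
        return [str(c) for c in self.counts.columns]

    def library(self, name: str) -> pd.Series:
        return self.counts[name]

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def select(self, libraries: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(libraries)].copy(),
            {l: self.metadata[l] for l in libraries},
        )

    def by_condition(self, condition: str) -> "CountMatrix":
        libs = [l for l in self.libraries if self.metadata[l].condition == condition]
        return self.select(libs)


def _metadata_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.yaml")


def read_counts(path: str | Path, metadata_path: str | Path | None = None) -> CountMatrix:
    """Read a species-by-library count TSV (first column ``species``).

    Metadata comes from ``metadata_path`` or, if present, the sidecar
    ``<path>.meta.yaml`` / ``<path>.meta.json``; otherwise every library
    defaults to unblocked.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    try:
        counts = df.apply(pd.to_numeric).astype("int64")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer cell: {exc}") from exc
    if not df.empty and not (df.apply(pd.to_numeric) == counts).all().all():
        bad = (df.apply(pd.to_numeric) != counts).stack()
        sp, lib = bad[bad].index[0]
        raise FormatError(f"{path}: non-integer count at species {sp!r}, library {lib!r}")

    meta: dict[str, LibraryMeta] = {}
    candidates = (
        [Path(metadata_path)]
        if metadata_path is not None
        else [_metadata_sidecar(path), path.with_name(path.name + ".meta.json")]
    )
    for cand in candidates:
        if cand.exists():
            raw = yaml.safe_load(cand.read_text())
            meta = {
                str(k): LibraryMeta(
                    condition=v.get("condition", "unblocked"),
                    replicate=str(v.get("replicate", "1")),
                    sample=str(v.get("sample", k)),
                )
                for k, v in (raw or {}).items()
            }
            break
    return CountMatrix(counts, meta)


def write_counts(matrix: CountMatrix, path: str | Path, with_metadata: bool = True) -> None:
    """Write a count TSV (and metadata sidecar) that round-trips bit-exactly."""
    path = Path(path)
    out = matrix.counts.copy()
    out.index.name = "species"
    with open(path, "w", newline="\n") as fh:
        out.to_csv(fh, sep="\t", lineterminator="\n")
    if with_metadata and matrix.metadata:
        sidecar = _metadata_sidecar(path)
        payload = {
            lib: {"condition": m.condition, "replicate": m.replicate, "sample": m.sample}
            for lib, m in matrix.metadata.items()
        }
        sidecar.write_text(yaml.safe_dump(payload, sort_keys=True))


def matrix_from_dict(
    data: Mapping[str, Mapping[str, int] | Iterable[int]],
    species: Sequence[str] | None = None,
    metadata: Mapping[str, LibraryMeta] | None = None,
) -> CountMatrix:
    """Convenience constructor: {library: {species: count}} -> CountMatrix."""
    df = pd.DataFrame(data, dtype="int64")
    if species is not None:
        df = df.reindex(list(species)).fillna(0).astype("int64")
    return CountMatrix(df, dict(metadata) if metadata else {})
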