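"""Dataset and sequence I/O.

siRNA records are 19-nt sense-strand sequences (identical to the target
site on the mRNA) with an optional observed efficacy, expressed as percent
inhibition of the target transcript in [0, 100].  ``T`` is accepted on
input as a synonym for ``U``; internally everything is RNA uppercase.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

SIRNA_LENGTH = 19
RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class ValidationError(ValueError):
    """Raised when an input sequence or table violates an invariant."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map DNA ``T`` to RNA ``U``.

    Raises :class:`ValidationError` listing any characters outside
    ``{A, C, G, U}`` after normalization.
    """
    norm = seq.strip().upper().replace("T", "U")
    bad = sorted(set(norm) - RNA_ALPHABET)
    if bad:
        raise ValidationError(
            f"sequence contains invalid characters {bad!r}; "
            "allowed alphabet is A, C, G, U (T accepted as U)"
        )
    return norm


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA sequence (antisense/guide strand)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SiRNARecord:
    """One 19-nt sense-strand siRNA with optional observed efficacy.

    Parameters
    ----------
    id : str
        Unique record identifier.
    sense_seq : str
        19-nt sequence over {A, C, G, U}; normalized on construction.
    efficacy : float or None
        Observed percent inhibition of the target mRNA, in [0, 100].
        ``None`` for unlabeled query records.
    """

    id: str
    sense_seq: str
    efficacy: float | None = None

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sense_seq)
        if len(seq) != SIRNA_LENGTH:
            raise ValidationError(
                f"record {self.id!r}: sequence length {len(seq)} != "
                f"{SIRNA_LENGTH} (siRNAs are 19-nt duplex cores)"
            )
        object.__setattr__(self, "sense_seq", seq)
        if self.efficacy is not None:
            eff = float(self.efficacy)
            if not 0.0 <= eff <= 100.0:
                raise ValidationError(
                    f"record {self.id!r}: efficacy {eff} outside [0, 100] "
                    "(% inhibition scale)"
                )
            object.__setattr__(self, "efficacy", eff)

    @property
    def antisense_seq(self) -> str:
        """Guide-strand sequence (reverse complement of the sense strand)."""
        return reverse_complement(self.sense_seq)


@dataclass
class Dataset:
    """An ordered collection of :class:`SiRNARecord` with unique ids."""

    records: list[SiRNARecord] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SiRNARecord]:
        return iter(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sense_seq for r in self.records]

    @property
    def efficacies(self) -> list[float]:
        vals = [r.efficacy for r in self.records]
        if any(v is None for v in vals):
            raise ValidationError(
                f"dataset {self.name!r} has unlabeled records; "
                "efficacy required here"
            )
        return vals  # type: ignore[return-value]

    @property
    def is_labeled(self) -> bool:
        return all(r.efficacy is not None for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sequence": [r.sense_seq for r in self.records],
                "efficacy": [r.efficacy for r in self.records],
            }
        )


def _sniff_delimiter(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is None:
        ext = os.path.splitext(os.fspath(path))[1].lower()
        fmt = "csv" if ext == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValidationError(f"unknown dataset format {fmt!r}; use tsv or csv")
    return "\t" if fmt == "tsv" else ","


def read_dataset(
    path: str | os.PathLike, format: str | None = None, require_labels: bool = True
) -> Dataset:
    """Read a delimited siRNA table with columns ``id, sequence, efficacy``.

    The delimiter is taken from ``format`` ("tsv"/"csv") or inferred from
    the file extension (``.csv`` means comma, anything else tab).  The
    efficacy column may be absent or empty when ``require_labels=False``.
    Rows violating a record invariant raise :class:`ValidationError` naming
    the offending row.
    """
    sep = _sniff_delimiter(path, format)
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "sequence": str})
    missing = {"id", "sequence"} - set(df.columns)
    if missing:
        raise ValidationError(f"dataset missing required columns {sorted(missing)}")
    has_eff = "efficacy" in df.columns
    if require_labels and not has_eff:
        raise ValidationError("training dataset requires an efficacy column")
    records: list[SiRNARecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # after header
        eff = getattr(row, "efficacy", None) if has_eff else None
        if eff is not None and pd.isna(eff):
            eff = None
        if require_labels and eff is None:
            raise ValidationError(f"row {i}: missing efficacy in labeled dataset")
        try:
            records.append(SiRNARecord(str(row.id), str(row.sequence), eff))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return Dataset(records, name=name)


def write_dataset(dataset: Dataset, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a dataset back to a delimited table (round-trips with read)."""
    sep = _sniff_delimiter(path, format)
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, normalized_sequence)`` pairs in file order.

    Arbitrary sequence lengths are allowed (target mRNAs as well as
    19-mers).  Empty files, empty sequences, and non-ACGU/T characters are
    rejected.
    """
    entries: list[tuple[str, str]] = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValidationError(f"FASTA record {rec.id!r} has an empty sequence")
        entries.append((rec.id, normalize_sequence(seq)))
    if not entries:
        raise ValidationError(f"no FASTA records found in {os.fspath(path)!r}")
    return entries


def enumerate_candidates(mrna_seq: str, parent_id: str = "mrna") -> list[SiRNARecord]:
    """Enumerate every 19-mer target-site window of an mRNA.

    Returns ``len(mrna) - 18`` unlabeled records; ids carry 1-based
    inclusive coordinates as ``<parent_id>:<start>-<end>``.
    """
    seq = normalize_sequence(mrna_seq)
    if len(seq) < SIRNA_LENGTH:
        raise ValidationError(
            f"mRNA length {len(seq)} < {SIRNA_LENGTH}; no candidate windows"
        )
    out = []
    for start in range(len(seq) - SIRNA_LENGTH + 1):
        window = seq[start : start + SIRNA_LENGTH]
        out.append(
            SiRNARecord(f"{parent_id}:{start + 1}-{start + SIRNA_LENGTH}", window)
        )
    return out


def dataset_from_arrays(
    sequences: Sequence[str],
    efficacies: Iterable[float] | None = None,
    name: str = "dataset",
    prefix: str = "s",
) -> Dataset:
    """Build a Dataset from parallel arrays, auto-numbering ids."""
    if efficacies is None:
        effs: list[float | None] = [None] * len(sequences)
    else:
        effs = list(efficacies)  # type: ignore[arg-type]
    records = [
        SiRNARecord(f"{prefix}{i + 1}", seq, eff)
        for i, (seq, eff) in enumerate(zip(sequences, effs, strict=True))
    ]
    return Dataset(records, name=name)
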