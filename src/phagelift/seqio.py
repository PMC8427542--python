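"""FASTA input and tabular report / label-table I/O.

The unit of prediction is a single nucleotide sequence (a contig or read).
Parsing is deliberately lossless: ambiguity codes are kept verbatim and only
resolved at encoding time.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

LIFESTYLES = ("virulent", "temperate")
DATASETS = ("curated", "auto")

#: IUPAC nucleotide codes accepted in input sequences.
IUPAC_CODES = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified DNA sequence; ``bases`` is upper-case."""

    id: str
    bases: str

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class PredictionRecord:
    """One classified sequence: score is P(virulent-derived) in [0, 1]."""

    id: str
    length: int
    score: float
    label: str  # "virulent" | "temperate" | "uncertain"


class FastaParseError(ValueError):
    pass


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> Iterator[NucleotideSequence]:
    """Yield sequences from a (optionally gzip-compressed) FASTA file.

    Records are yielded in file order with bases upper-cased, surrounding
    whitespace stripped, and multi-line sequences concatenated. Duplicate ids
    are disambiguated with an ordinal suffix (``id``, ``id.2``, ``id.3``, ...)
    and a warning is logged, so that ids can key a per-record report.

    Raises
    ------
    FastaParseError
        If sequence data precedes the first header line.
    """
    seen: dict[str, int] = {}
    header: str | None = None
    chunks: list[str] = []
    n_records = 0

    def _emit() -> NucleotideSequence:
        assert header is not None
        name = header.split()[0] if header.split() else header
        if not name:
            raise FastaParseError("empty FASTA header")
        count = seen.get(name, 0) + 1
        seen[name] = count
        if count > 1:
            logger.warning("duplicate FASTA id %r renamed to %r", name, f"{name}.{count}")
            name = f"{name}.{count}"
        return NucleotideSequence(id=name, bases="".join(chunks).upper())

    with _open_text(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    n_records += 1
                    yield _emit()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
        if header is not None:
            n_records += 1
            yield _emit()
    if n_records == 0:
        logger.warning("no FASTA records found in %s", path)


def write_fasta(records: Iterable[NucleotideSequence], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                handle.write(rec.bases[i : i + width] + "\n")


REPORT_COLUMNS = ["id", "length", "score", "label"]


def write_prediction_report(records: Iterable[PredictionRecord], path: str | Path) -> None:
    """Write a TSV report (id, length, score, label), score with 4 decimals."""
    rows = [(r.id, r.length, f"{r.score:.4f}", r.label) for r in records]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_prediction_report(path: str | Path) -> list[PredictionRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"prediction report {path} lacks columns {missing}")
    return [
        PredictionRecord(str(r.id), int(r.length), float(r.score), str(r.label))
        for r in df.itertuples(index=False)
    ]


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read a lifestyle label table (TSV: genome_id, lifestyle, dataset).

    Every genome appears exactly once; lifestyle is 'virulent' or 'temperate';
    dataset is 'curated' (manually annotated) or 'auto' (computationally
    labelled, training-only).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_label_table(df)


def validate_label_table(df: pd.DataFrame) -> pd.DataFrame:
    required = ["genome_id", "lifestyle", "dataset"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"label table lacks columns {missing}")
    dup = df["genome_id"][df["genome_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate genome ids in label table: {sorted(set(dup))}")
    bad = set(df["lifestyle"]) - set(LIFESTYLES)
    if bad:
        raise ValueError(f"unknown lifestyle values: {sorted(bad)}")
    bad = set(df["dataset"]) - set(DATASETS)
    if bad:
        raise ValueError(f"unknown dataset values: {sorted(bad)}")
    return df.reset_index(drop=True)


def write_label_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_label_table(df).to_csv(path, sep="\t", index=False)
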