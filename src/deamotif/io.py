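"""FASTA input, motif configuration files, and report serialization.

The motif configuration format is one motif per line::

    # pattern [, name=LABEL] [, target=INT] [, strands=top|bottom|both]
    TAC, target=2, strands=both
    WRC
    CG, target=0, strands=top

``target`` defaults to the rightmost literal C of the pattern and
``strands`` to ``both``.  Blank lines and ``#`` comments are ignored.

Reports serialize either as plain-text keyword/value lines
(``key<TAB>value``, 3 significant digits, missing values as ``NA``) or
as a full-precision TSV table; metadata travels as leading ``#`` lines.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

from Bio import SeqIO

from .codons import CodingSequence, SequenceValidationError
from .motifs import MotifConfigError, MotifSpec, default_motif_set
from .stats import RepresentationReport

logger = logging.getLogger(__name__)


def normalize_sequence(raw: str, identifier: str = "") -> str:
    """Upper-case and map RNA U to T (with a warning); no other rewriting."""
    s = raw.upper()
    if "U" in s:
        logger.warning(
            "%s: RNA-style U nucleotides mapped to T", identifier or "sequence"
        )
        s = s.replace("U", "T")
    return s


def read_fasta(
    path: str | Path,
    *,
    strict_stops: bool = False,
) -> list[CodingSequence]:
    """Parse a FASTA file of in-frame coding sequences.

    Each record must be a positive multiple of 3 over A/C/G/T after
    normalization; violations raise :class:`SequenceValidationError`
    naming the record.  Internal stop codons are accepted with a logged
    warning (viral ORF annotations sometimes include them) unless
    ``strict_stops=True``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceValidationError(f"{path}: no FASTA records found")
    sequences = []
    for rec in records:
        seq = CodingSequence(
            normalize_sequence(str(rec.seq), rec.id), rec.description
        )
        stops = seq.internal_stop_positions()
        if stops:
            msg = (
                f"{rec.id}: internal stop codon(s) at codon index "
                f"{stops} — sequence accepted, but check the reading frame"
            )
            if strict_stops:
                raise SequenceValidationError(msg)
            logger.warning(msg)
        sequences.append(seq)
    return sequences


def parse_motif_config(path: str | Path | None) -> list[MotifSpec]:
    """Read a motif configuration file; ``None`` yields the default set."""
    if path is None:
        return default_motif_set()
    text = Path(path).read_text()
    motifs: list[MotifSpec] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split(",")]
        pattern = fields[0]
        kwargs: dict[str, object] = {}
        for f in fields[1:]:
            if "=" not in f:
                raise MotifConfigError(
                    f"{path}:{lineno}: expected key=value, got {f!r}"
                )
            key, _, val = f.partition("=")
            key, val = key.strip().lower(), val.strip()
            if key == "target":
                try:
                    kwargs["target_index"] = int(val)
                except ValueError as exc:
                    raise MotifConfigError(
                        f"{path}:{lineno}: target must be an integer"
                    ) from exc
            elif key == "strands":
                kwargs["strand_mode"] = val.lower()
            elif key == "name":
                kwargs["name"] = val
            else:
                raise MotifConfigError(
                    f"{path}:{lineno}: unknown option {key!r}"
                )
        try:
            motifs.append(MotifSpec(pattern, **kwargs))
        except MotifConfigError as exc:
            raise MotifConfigError(f"{path}:{lineno}: {exc}") from exc
    if not motifs:
        raise MotifConfigError(f"{path}: no motifs defined")
    return motifs


# ---------------------------------------------------------------------------
# report serialization


def _format_value(v, precision: int | None) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    if isinstance(v, (int,)) and not isinstance(v, bool):
        return str(v)
    if precision is None:
        return repr(float(v))
    return f"{float(v):.{precision}g}"


def format_report(report: RepresentationReport, fmt: str = "kv") -> str:
    """Serialize a report: ``kv`` (3 significant digits) or ``tsv`` (full
    double precision)."""
    if fmt not in ("kv", "tsv"):
        raise ValueError(f"unknown report format {fmt!r}")
    precision = 3 if fmt == "kv" else None
    lines = [f"# {k}\t{v}" for k, v in report.metadata.items()]
    if fmt == "tsv":
        lines.append("key\tvalue")
    lines.extend(
        f"{k}\t{_format_value(v, precision)}" for k, v in report.values.items()
    )
    return "\n".join(lines) + "\n"


def write_report(report: RepresentationReport, path: str | Path, fmt: str = "kv") -> None:
    Path(path).write_text(format_report(report, fmt))


def read_report(path: str | Path) -> RepresentationReport:
    """Parse a serialized report back into key/value + metadata form.

    Values parse as int where possible, else float; ``NA`` becomes
    ``None``.  Round-trips exactly for ``tsv`` output.
    """
    values: dict[str, float | int | None] = {}
    metadata: dict[str, object] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("\t")
            metadata[key] = val
            continue
        key, _, val = line.partition("\t")
        if key == "key" and val == "value":  # tsv header
            continue
        if val == "NA":
            values[key] = None
        else:
            try:
                values[key] = int(val)
            except ValueError:
                values[key] = float(val)
    return RepresentationReport(values=values, metadata=metadata)
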