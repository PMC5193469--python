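"""File formats: per-nucleus TSV, cutoff config, call tables.

Per-nucleus counts travel as tab-delimited text with a required header
``case_id  chromosome  nucleus_id  n_red  n_green``; malformed rows are
reported with their line numbers.  Cutoffs are a YAML mapping
chromosome -> {deletion_cutoff, imbalance_cutoff} plus a ``source``
key.  Call tables are written as CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .caller import NucleusCount, SampleCall
from .chromosomes import CHROM_PAIRS, ChromCutoffs, CutoffSet, TARGET_ARM

NUCLEUS_COLUMNS = ["case_id", "chromosome", "nucleus_id", "n_red", "n_green"]


class ParseError(ValueError):
    """Malformed input file; message lists the offending lines."""


def load_nucleus_counts(path: str | Path) -> dict[tuple[str, str], list[NucleusCount]]:
    """Read a per-nucleus TSV into (case_id, chromosome) -> counts.

    Raises :class:`ParseError` naming every malformed line (missing
    fields, unknown chromosome, negative or non-integer counts).
    """
    path = Path(path)
    out: dict[tuple[str, str], list[NucleusCount]] = {}
    errors: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != NUCLEUS_COLUMNS:
            raise ParseError(
                f"{path}: expected header {NUCLEUS_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                errors.append(f"line {lineno}: expected 5 fields, got {len(parts)}")
                continue
            case_id, chrom, nucleus_id, red_s, green_s = parts
            if chrom not in CHROM_PAIRS:
                errors.append(f"line {lineno}: unknown chromosome {chrom!r}")
                continue
            try:
                nuc = NucleusCount(nucleus_id, int(red_s), int(green_s))
            except (TypeError, ValueError) as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            out.setdefault((case_id, chrom), []).append(nuc)
    if errors:
        raise ParseError(f"{path}: {len(errors)} malformed row(s): "
                         + "; ".join(errors))
    return out


def write_nucleus_counts(
    records: dict[tuple[str, str], list[NucleusCount]], path: str | Path
) -> None:
    """Write per-nucleus counts as TSV (inverse of load_nucleus_counts)."""
    with open(path, "w") as fh:
        fh.write("\t".join(NUCLEUS_COLUMNS) + "\n")
        for (case_id, chrom), nuclei in records.items():
            for nuc in nuclei:
                fh.write(f"{case_id}\t{chrom}\t{nuc.nucleus_id}\t"
                         f"{nuc.n_red}\t{nuc.n_green}\n")


def load_cutoffs(path: str | Path) -> CutoffSet:
    """Read a YAML cutoff config into a CutoffSet."""
    raw = yaml.safe_load(Path(path).read_text())
    per_chrom = {
        chrom: ChromCutoffs(float(v["deletion_cutoff"]),
                            float(v["imbalance_cutoff"]))
        for chrom, v in raw.items() if chrom in CHROM_PAIRS
    }
    if not per_chrom:
        raise ParseError(f"{path}: no chromosome entries found")
    return CutoffSet(per_chrom=per_chrom, source=raw.get("source", "file"))


def write_cutoffs(cutoffs: CutoffSet, path: str | Path) -> None:
    doc: dict = {"source": cutoffs.source}
    for chrom, cut in cutoffs.per_chrom.items():
        doc[chrom] = {
            "deletion_cutoff": round(cut.deletion_cutoff, 4),
            "imbalance_cutoff": round(cut.imbalance_cutoff, 4),
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def calls_to_frame(calls: dict[str, dict[str, SampleCall]]) -> pd.DataFrame:
    """Flatten {case_id: {chrom_id: SampleCall}} into a call table."""
    rows = []
    for case_id, per_chrom in calls.items():
        for chrom_id, call in per_chrom.items():
            s = call.summary
            rows.append({
                "case_id": case_id,
                "chromosome": chrom_id,
                "target_arm": TARGET_ARM[chrom_id],
                "status": call.target_status.value,
                "control_arm_deleted": call.control_arm_deleted,
                "n_total": s.n_total,
                "n_analyzable": s.n_analyzable,
                "pct_deleted": round(s.pct_deleted, 2) if s.n_analyzable else None,
                "pct_imbalanced": round(s.pct_imbalanced, 2) if s.n_analyzable else None,
                "pct_monosomy": round(s.pct_monosomy, 2) if s.n_analyzable else None,
                "qc_pass": call.qc_pass,
                "qc_reason": call.qc_reason,
            })
    return pd.DataFrame(rows)
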