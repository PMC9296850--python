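"""Run configuration and tabular reports.

The report tables mirror the conventional assembly-evaluation layout:
per-assembly contig statistics with NGA50/LGA50 ("n.s.d." when not
defined), IR length and equality ("n.a." when no circular genome or IR
exists), and the annotation audit table.  The run configuration captures
every tunable constant of the pipeline with the standard defaults; every
run can write its resolved configuration next to its outputs so results
are reproducible from the emitted file alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence

import pandas as pd
import yaml

from .metrics import MetricsRecord
from .postprocess import Provenance

__all__ = ["RunConfig", "NOT_DEFINED", "NOT_APPLICABLE", "metrics_table", "table_report"]

NOT_DEFINED = "n.s.d."
NOT_APPLICABLE = "n.a."


@dataclass
class RunConfig:
    """All tunable pipeline constants, with their standard defaults."""

    cap_levels: tuple = (2000, 1000, 500, 250, 100, 50)
    window: int = 250
    low_coverage_fraction: float = 0.5
    min_overlap: int = 15
    motif_len: int = 25
    max_mismatch: int = 3
    end_window: int = 100
    min_contig: int = 100
    min_identity: float = 0.95
    min_ir_len: int = 1000
    kmer_size: int = 31
    anchor_k: int = 21
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "cap_levels" in data:
            data["cap_levels"] = tuple(data["cap_levels"])
        return cls(**data)


def _cell(value, undefined=NOT_DEFINED):
    if value is None:
        return undefined
    if isinstance(value, bool):
        return "Yes" if value else "No"
    return value


def metrics_table(
    records: Sequence[MetricsRecord],
    provenances: Optional[Sequence[Provenance]] = None,
) -> pd.DataFrame:
    """Assembly statistics table, one row per assembly.

    NGA50/LGA50 render as "n.s.d." when undefined; IR columns render as
    "n.a." when the assembly never became a circular genome with an IR.
    """
    if provenances is None:
        provenances = [Provenance() for _ in records]
    rows = []
    for rec, prov in zip(records, provenances):
        rows.append(
            {
                "Asmb.": prov.software,
                "Cov.": prov.cap_level if prov.cap_level is not None else "orig.",
                "Repl.": prov.replicate or "",
                "Seed": prov.seed_label or "",
                "Contigs": rec.n_contigs,
                "Largest contig (bp)": rec.largest_contig,
                "NGA50 (bp)": _cell(rec.nga50, NOT_DEFINED),
                "LGA50": _cell(rec.lga50, "-"),
                "IR length (bp)": _cell(rec.ir_length, NOT_APPLICABLE),
                "IR equal.": _cell(rec.ir_equal, NOT_APPLICABLE),
            }
        )
    columns = [
        "Asmb.", "Cov.", "Repl.", "Seed", "Contigs", "Largest contig (bp)",
        "NGA50 (bp)", "LGA50", "IR length (bp)", "IR equal.",
    ]
    return pd.DataFrame(rows, columns=columns)


def table_report(records, provenances=None, path=None, fmt: str = "tsv"):
    """Render a metrics table to TSV or Markdown; returns the DataFrame."""
    df = metrics_table(records, provenances)
    if path is not None:
        if fmt == "tsv":
            df.to_csv(path, sep="\t", index=False)
        elif fmt == "markdown":
            with open(path, "w") as fh:
                fh.write(df.to_markdown(index=False))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return df
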