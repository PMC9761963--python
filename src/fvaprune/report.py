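"""Tabular and JSON output of FVA results."""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import TextIO

from .fva import FVAResult, conventional_lp_count
from .model import MetabolicModel

__all__ = ["RunStats", "write_result_tsv", "write_stats_json"]

TSV_COLUMNS = ("reaction_id", "minimum", "maximum", "min_method", "max_method")


@dataclass
class RunStats:
    """Summary accounting of one FVA run.

    ``lp_ratio`` is the fraction of the conventional 2n+1 LPs actually
    solved; the removal categories (inspected / reused / fixed) sum to
    ``lps_removed``.
    """

    model_name: str
    n_reactions: int
    n_metabolites: int
    Z0: float
    mu: float
    lps_solved: int
    lps_removed: int
    lps_conventional: int
    lp_ratio: float
    removed_by_inspection: int
    removed_by_reuse: int
    removed_fixed: int

    @classmethod
    def from_result(cls, result: FVAResult, model: MetabolicModel) -> "RunStats":
        total = conventional_lp_count(result.n)
        removed = result.removal_counts()
        return cls(
            model_name=model.name,
            n_reactions=model.n,
            n_metabolites=model.m,
            Z0=result.Z0,
            mu=result.mu,
            lps_solved=result.lps_solved,
            lps_removed=result.lps_removed,
            lps_conventional=total,
            lp_ratio=result.lps_solved / total if total else 1.0,
            removed_by_inspection=removed["inspected"],
            removed_by_reuse=removed["reused"],
            removed_fixed=removed["fixed"],
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _fmt(x: float) -> str:
    # 12 significant digits; infinities as bare inf/-inf for parseability
    if x == float("inf"):
        return "inf"
    if x == float("-inf"):
        return "-inf"
    return f"{x:.12g}"


def write_result_tsv(result: FVAResult, model: MetabolicModel,
                     path: str | Path | TextIO) -> None:
    """Write per-reaction extents as TSV, one row per reaction in model order."""
    own = isinstance(path, (str, Path))
    fh = open(path, "w") if own else path
    try:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for i, rid in enumerate(result.reaction_ids):
            fh.write(
                "\t".join(
                    (
                        rid,
                        _fmt(result.v_min[i]),
                        _fmt(result.v_max[i]),
                        result.method_min[i],
                        result.method_max[i],
                    )
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()


def write_stats_json(stats: RunStats, path: str | Path | None) -> None:
    """Write run statistics as JSON; path ``None`` or ``"-"`` means stdout."""
    text = stats.to_json() + "\n"
    if path is None or str(path) == "-":
        sys.stdout.write(text)
    else:
        Path(path).write_text(text)
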