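"""Tabular rendering of scan results, mirroring the conventional layout."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .contingency import AssociationResult

__all__ = ["format_p", "results_to_dataframe", "write_results"]


def format_p(p: float, paper_style: bool = False) -> str:
    """``1.89e-21`` by default; ``1.89X10^-21`` with ``paper_style``."""
    if p >= 0.0001:
        return f"{p:.4f}"
    text = f"{p:.2e}"
    mant, expo = text.split("e")
    expo_i = int(expo)
    if paper_style:
        return f"{mant}X10^{expo_i}"
    return f"{mant}e{expo_i}"


def results_to_dataframe(
    results: Sequence[AssociationResult],
    paper_style: bool = False,
) -> pd.DataFrame:
    """One row per unit in the published column order.

    ``pc`` renders as the corrected value, ``NS`` for units whose
    uncorrected P is >= 0.05, or empty when no correction was requested.
    """
    rows = []
    for r in results:
        if r.pc is None:
            pc = ""
        elif r.ns:
            pc = "NS"
        else:
            pc = format_p(r.pc, paper_style)
        rows.append(
            {
                "unit": r.unit,
                "case_carriers": r.table.a,
                "case_total": r.table.case_total,
                "case_freq_pct": round(r.case_frequency, 1),
                "control_carriers": r.table.c,
                "control_total": r.table.control_total,
                "control_freq_pct": round(r.control_frequency, 1),
                "p": format_p(r.p, paper_style),
                "or": round(r.or_, 2),
                "pc": pc,
                "ci_low": round(r.ci_low, 2),
                "ci_high": round(r.ci_high, 2),
                "direction": r.direction.value,
            }
        )
    return pd.DataFrame(rows)


def write_results(
    results: Sequence[AssociationResult],
    path,
    provenance: str | None = None,
    paper_style: bool = False,
) -> None:
    df = results_to_dataframe(results, paper_style)
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)
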