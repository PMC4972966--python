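"""Cross-genome statistics and summary tables.

Provides the 2x2 chi-square comparison (Yates-corrected by default) used
to contrast retrogene and intronless-gene content between genomes, and the
report bundle: candidate counts by structural class, candidates by
parental-source species, per-branch event counts, hallmark and orphan
tallies.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .detection import RetrogeneCandidate
from .events import EvolutionaryEventCall, summarize_events
from .selection import DnDsResult

__all__ = ["ContingencyTable2x2", "chi_square_2x2", "build_reports", "write_reports"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = the two species, columns = in-class / out-of-class counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        arr = self.to_array()
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise ValueError("all margins must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def chi_square_2x2(
    table: ContingencyTable2x2 | list | tuple, continuity_correction: bool = True
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, Yates-corrected by default.

    Returns (statistic, p_value) with p from a chi-square with 1 df.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    res = chi2_contingency(table.to_array(), correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def build_reports(
    candidates: list[RetrogeneCandidate],
    event_calls: list[EvolutionaryEventCall],
    dnds: dict[str, DnDsResult] | None = None,
    functional: dict[str, bool] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the summary tables of one analysis run."""
    dnds = dnds or {}
    functional = functional or {}
    species = sorted({c.retro_species for c in candidates})

    rows = []
    for sp in species:
        sub = [c for c in candidates if c.retro_species == sp]
        rows.append(
            {
                "species": sp,
                "intact": sum(c.structural_class == "intact" for c in sub),
                "incomplete": sum(c.structural_class == "incomplete" for c in sub),
                "total": len(sub),
            }
        )
    by_class = pd.DataFrame(rows, columns=["species", "intact", "incomplete", "total"])

    src_rows = []
    for c in candidates:
        src_species = ",".join(sorted({p.parent_species for p in c.parents}))
        src_rows.append({"retro_species": c.retro_species, "parent_source": src_species})
    by_source = (
        pd.DataFrame(src_rows)
        .groupby(["parent_source", "retro_species"])
        .size()
        .unstack(fill_value=0)
        .reset_index()
        if src_rows
        else pd.DataFrame(columns=["parent_source"])
    )

    hallmark_rows = []
    for sp in species:
        sub = [c for c in candidates if c.retro_species == sp]
        hallmark_rows.append(
            {
                "species": sp,
                "polyA": sum(c.polyA_found for c in sub),
                "tsd": sum(c.tsd_found for c in sub),
                "orphan": sum(c.orphan for c in sub),
                "utr_exon_gain": sum(c.utr_exon_gain for c in sub),
                "n_terminal_extension": sum(c.n_terminal_extension for c in sub),
                "functional": sum(functional.get(c.retro_gene_id, False) for c in sub),
                "total": len(sub),
            }
        )
    hallmarks = pd.DataFrame(hallmark_rows)

    dnds_rows = []
    for c in candidates:
        r = dnds.get(c.retro_gene_id)
        dnds_rows.append(
            {
                "candidate": c.retro_gene_id,
                "species": c.retro_species,
                "parent": c.parental_gene_id,
                "parent_species": c.parental_species,
                "class": c.structural_class,
                "orphan": c.orphan,
                "dN": r.dn if r else float("nan"),
                "dS": r.ds if r else float("nan"),
                "omega": r.omega if r else float("nan"),
                "lrt_p": r.p_value if r else float("nan"),
                "saturated": r.saturated if r else False,
                "functional": functional.get(c.retro_gene_id, False),
            }
        )
    dnds_table = pd.DataFrame(
        dnds_rows,
        columns=[
            "candidate", "species", "parent", "parent_species", "class",
            "orphan", "dN", "dS", "omega", "lrt_p", "saturated", "functional",
        ],
    )

    return {
        "candidates_by_class": by_class,
        "candidates_by_source": by_source,
        "events_by_branch": summarize_events(event_calls),
        "hallmarks": hallmarks,
        "dnds": dnds_table,
    }


def write_reports(bundle: dict[str, pd.DataFrame], out_dir: str) -> None:
    """One TSV per table plus a plain-text overview."""
    os.makedirs(out_dir, exist_ok=True)
    for name, df in bundle.items():
        df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
        for name, df in bundle.items():
            fh.write(f"== {name} ==\n")
            fh.write(df.to_string(index=False))
            fh.write("\n\n")
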