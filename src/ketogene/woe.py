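"""Weight-of-Evidence scoring of genotype categories against ketosis.

For a categorical predictor and a binary outcome, each category's Weight of
Evidence is

    WoE = ln( relative frequency of goods / relative frequency of bads ) * 100

where "goods" are healthy animals (status 0), "bads" are subclinical-ketosis
animals (status 1), and a category's relative frequency is its share of the
respective outcome margin. Higher WoE means the category is enriched among
the healthy — for the osteopontin c.495C>T locus the TT genotype scores
highest, i.e. is associated with resistance.

Categories with similar WoE carry similar risk information and can be
pooled: :func:`merge_similar` greedily merges the closest pair while their
gap stays below a threshold, recomputing WoE from the pooled counts. The
Information Value summarizes the whole table's predictive strength.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .association import GENOTYPE_ORDER, GenotypeOutcomeTable
from .exceptions import (
    DegenerateOutcomeError,
    ParameterError,
    UnknownCategoryError,
    ZeroCellError,
)

#: WoE-unit scale factor as conventionally printed (natural log x 100).
WOE_SCALE = 100.0


@dataclass(frozen=True)
class WoEEntry:
    """One category's goods/bads counts and Weight of Evidence."""

    category: str
    goods: int
    bads: int
    rel_freq_goods: float
    rel_freq_bads: float
    woe: float
    merged_from: tuple[str, ...] = ()

    @property
    def members(self) -> tuple[str, ...]:
        """Original categories this entry covers (itself if never merged)."""
        return self.merged_from if self.merged_from else (self.category,)


@dataclass(frozen=True)
class WoETable:
    """Ordered WoE entries plus outcome margins and the merge history."""

    entries: tuple[WoEEntry, ...]
    total_goods: int
    total_bads: int
    merge_log: tuple[str, ...] = ()

    def __getitem__(self, category: str) -> WoEEntry:
        for entry in self.entries:
            if entry.category == category or category in entry.members:
                return entry
        raise UnknownCategoryError(category)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "category": e.category,
                    "goods": e.goods,
                    "bads": e.bads,
                    "rel_freq_goods": e.rel_freq_goods,
                    "rel_freq_bads": e.rel_freq_bads,
                    "woe": e.woe,
                    "merged_from": "+".join(e.merged_from),
                }
                for e in self.entries
            ]
        )


def _entry(
    category: str,
    goods: int,
    bads: int,
    total_goods: int,
    total_bads: int,
    zero_cell_policy: str,
    merged_from: tuple[str, ...] = (),
) -> WoEEntry:
    g, b = float(goods), float(bads)
    if goods == 0 or bads == 0:
        if zero_cell_policy == "error":
            raise ZeroCellError(f"category {category!r} has an empty cell")
        if zero_cell_policy != "continuity":
            raise ParameterError(f"unknown zero_cell_policy {zero_cell_policy!r}")
        warnings.warn(
            f"category {category!r} has an empty cell; continuity-corrected (+0.5)",
            stacklevel=3,
        )
        g, b = g + 0.5, b + 0.5
    rf_g = g / total_goods
    rf_b = b / total_bads
    return WoEEntry(
        category=category,
        goods=goods,
        bads=bads,
        rel_freq_goods=rf_g,
        rel_freq_bads=rf_b,
        woe=math.log(rf_g / rf_b) * WOE_SCALE,
        merged_from=merged_from,
    )


def compute_woe(
    table: GenotypeOutcomeTable, zero_cell_policy: str = "continuity"
) -> WoETable:
    """Build the per-genotype WoE table from a 2x3 outcome table.

    Goods are the status-0 (healthy) row, bads the status-1 (SCK) row.
    Under the ``continuity`` policy a category containing a zero cell gets
    0.5 added to both of its cells before its relative frequencies are
    formed; under ``error`` a zero cell raises.
    """
    total_goods = int(table.row_totals[0])
    total_bads = int(table.row_totals[1])
    if total_goods == 0 or total_bads == 0:
        raise DegenerateOutcomeError("WoE needs both healthy and SCK animals present")
    entries = tuple(
        _entry(
            g,
            table.cell(0, g),
            table.cell(1, g),
            total_goods,
            total_bads,
            zero_cell_policy,
        )
        for g in GENOTYPE_ORDER
    )
    return WoETable(entries=entries, total_goods=total_goods, total_bads=total_bads)


def merge_similar(woe_table: WoETable, max_gap: float = 30.0) -> WoETable:
    """Greedily pool categories whose WoE values differ by at most ``max_gap``.

    Repeatedly merges the pair with the smallest absolute WoE difference
    while that difference is <= ``max_gap``; the pooled category's WoE is
    recomputed from its pooled counts. Ties are broken toward the leftmost
    pair in table order. ``max_gap = 0`` merges only exactly tied pairs
    (identical categories) and otherwise leaves the table unchanged.
    """
    if max_gap < 0:
        raise ParameterError("max_gap must be >= 0")
    if len(woe_table.entries) < 2:
        raise ParameterError("merging needs at least two categories")

    entries = list(woe_table.entries)
    log = list(woe_table.merge_log)
    while len(entries) >= 2:
        best = None
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                gap = abs(entries[i].woe - entries[j].woe)
                if best is None or gap < best[0] - 1e-12:
                    best = (gap, i, j)
        gap, i, j = best
        if gap > max_gap:
            break
        a, b = entries[i], entries[j]
        members = a.members + b.members
        merged = _entry(
            "+".join(members),
            a.goods + b.goods,
            a.bads + b.bads,
            woe_table.total_goods,
            woe_table.total_bads,
            "continuity",
            merged_from=members,
        )
        log.append(f"merged {a.category} + {b.category} (gap {gap:.3f})")
        entries = [e for k, e in enumerate(entries) if k not in (i, j)]
        entries.insert(i, merged)
    return WoETable(
        entries=tuple(entries),
        total_goods=woe_table.total_goods,
        total_bads=woe_table.total_bads,
        merge_log=tuple(log),
    )


def information_value(woe_table: WoETable) -> float:
    """IV = sum over categories of (rel_freq_goods - rel_freq_bads) * WoE/100.

    Each term is a product of same-sign factors, so IV >= 0; 0 means the
    predictor carries no information about the outcome.
    """
    return sum(
        (e.rel_freq_goods - e.rel_freq_bads) * (e.woe / WOE_SCALE)
        for e in woe_table.entries
    )


def woe_score(record_genotype: str, woe_table: WoETable) -> float:
    """Per-animal predictor: the WoE of the (possibly merged) category."""
    return woe_table[record_genotype].woe


def plot_woe(woe_table: WoETable, path=None):
    """Bar plot of WoE per category (positive = associated with health)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    cats = [e.category for e in woe_table.entries]
    vals = [e.woe for e in woe_table.entries]
    ax.bar(cats, vals, color=["tab:green" if v > 0 else "tab:red" for v in vals])
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_ylabel("Weight of Evidence")
    ax.set_xlabel("osteopontin genotype")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
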