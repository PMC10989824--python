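"""Active/inactive calling per tissue and the core / tissue-specific partition.

A locus is *active* in a tissue when it shows at least ``min_count`` reads
in at least ``min_replicates`` replicates of that tissue (defaults 1 and 1:
presence of any transcript).  Active loci common to all tissues are *core*;
loci active in exactly one tissue are tissue-specific (*exclusive*); the
rest are *shared* by the named subset of tissues.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage truncated toward zero at ``decimals`` decimal places.

    percent(59514, 161205) == 36.9; percent(1, 3) == 33.3.
    """
    if denominator == 0:
        raise ZeroDivisionError("percent: denominator is zero")
    scale = 10**decimals
    if isinstance(numerator, int) and isinstance(denominator, int):
        value = (100 * scale * numerator) // denominator
    else:
        value = math.floor(100 * scale * numerator / denominator)
    return value / scale


def partition_label(active_tissues: frozenset, all_tissues: tuple[str, ...]) -> str:
    if not active_tissues:
        return "inactive"
    if len(active_tissues) == len(all_tissues):
        return "core"
    if len(active_tissues) == 1:
        return f"exclusive:{next(iter(active_tissues))}"
    return "shared:" + "+".join(sorted(active_tissues))


@dataclass
class ActivityTable:
    """Per-locus per-tissue active flags plus partition labels."""

    flags: pd.DataFrame  # loci x tissues, bool
    labels: pd.Series  # loci -> partition label

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self.flags.columns)

    def active_set(self, locus_id: str) -> frozenset:
        row = self.flags.loc[locus_id]
        return frozenset(row.index[row])

    def active_in(self, tissue: str) -> pd.Index:
        return self.flags.index[self.flags[tissue]]

    def write(self, path: str | Path) -> None:
        out = self.flags.astype(int).copy()
        out["label"] = self.labels
        out.to_csv(path, sep="\t", index_label="locus_id")


def call_active(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    min_count: int = 1,
    min_replicates: int = 1,
) -> ActivityTable:
    """Call per-tissue activity from a loci x samples count matrix.

    Active in tissue t iff count >= min_count in >= min_replicates
    replicates of t.
    """
    tissues = sorted(sample_sheet["tissue"].unique())
    flags = {}
    for t in tissues:
        samples = sample_sheet.index[sample_sheet["tissue"] == t]
        samples = [s for s in counts.columns if s in set(samples)]
        if not samples:
            raise ValueError(f"tissue {t} has no samples in the count matrix")
        sub = counts[samples]
        flags[t] = (sub >= min_count).sum(axis=1) >= min_replicates
    flag_df = pd.DataFrame(flags)
    ts = tuple(tissues)
    labels = flag_df.apply(
        lambda row: partition_label(frozenset(row.index[row]), ts), axis=1
    )
    if len(flag_df) == 0:
        labels = pd.Series(dtype=object)
    return ActivityTable(flags=flag_df, labels=labels)


def venn_summary(table: ActivityTable) -> dict:
    """Counts per region of the k-set Venn over tissues, plus totals.

    Region keys join the tissue subset with ``&`` (e.g. ``"lung&trachea"``
    for loci active in exactly those two tissues).  The identity
    per-tissue total = sum of regions containing the tissue is enforced.
    """
    tissues = table.tissues
    if len(tissues) < 2:
        raise ValueError("venn_summary needs >= 2 tissues")
    regions: dict[frozenset, int] = {}
    for size in range(1, len(tissues) + 1):
        for combo in combinations(tissues, size):
            regions[frozenset(combo)] = 0
    union = 0
    for _, row in table.flags.iterrows():
        active = frozenset(row.index[row])
        if active:
            regions[active] += 1
            union += 1
    per_tissue = {
        t: sum(n for s, n in regions.items() if t in s) for t in tissues
    }
    for t in tissues:
        check = sum(n for s, n in regions.items() if t in s)
        assert check == per_tissue[t]
    core = regions[frozenset(tissues)]
    summary = {
        "tissues": list(tissues),
        "regions": {"&".join(sorted(s)): n for s, n in regions.items()},
        "per_tissue": per_tissue,
        "exclusive": {t: regions[frozenset([t])] for t in tissues},
        "core": core,
        "union": union,
        "inactive": int((~table.flags.any(axis=1)).sum()),
        "percent_core_of_active": percent(core, union) if union else None,
        "percent_tissue_specific_of_active": (
            percent(sum(regions[frozenset([t])] for t in tissues), union)
            if union
            else None
        ),
    }
    return summary


def write_venn(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
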