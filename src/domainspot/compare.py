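"""Overlap of significant-hotspot landscapes across TS, OG and genome runs.

Two resolutions: shared domain families, and shared (family, MSA column)
positions. "Co-located" means an identical (family, column) of the same
mutation class — hotspots are compared inside the family alignment, and
no positional tolerance window is applied. Genome-wide hotspots that
co-locate with a cancer-gene hotspot but involve proteins not labelled
TS/OG are reported as putative gain-of-function (OG match) or
loss-of-function (TS match) candidates; a column matching both sides is
reported as ambiguous, never silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: The 7 disjoint intersection regions of three sets.
REGIONS = ("TS_only", "OG_only", "genome_only", "TS_OG", "TS_genome",
           "OG_genome", "TS_OG_genome")


@dataclass
class OverlapSummary:
    mclass: str
    level: str  # "family" or "position"
    region_counts: dict  # region name -> count
    shared_items: dict  # region name -> sorted list of keys

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())


def _keys(tests, level: str) -> set:
    if level == "family":
        return {t.family_id for t in tests}
    if level == "position":
        return {(t.family_id, t.msa_column) for t in tests}
    raise ValueError(f"unknown overlap level {level!r}")


def _check_class(tests, mclass: str, name: str) -> None:
    bad = {t.mclass for t in tests} - {mclass}
    if bad:
        raise ValueError(f"{name} hotspots carry foreign classes {sorted(bad)}")


def overlap_sets(ts_hotspots, og_hotspots, genome_hotspots, level: str,
                 mclass: str) -> OverlapSummary:
    """Exact set algebra over the three significant-hotspot collections.

    Region counts are of the 7 disjoint intersection regions, so they sum
    to the size of the union.
    """
    for tests, name in ((ts_hotspots, "TS"), (og_hotspots, "OG"),
                        (genome_hotspots, "genome")):
        _check_class(tests, mclass, name)
    ts, og, ge = (_keys(t, level) for t in (ts_hotspots, og_hotspots,
                                            genome_hotspots))
    regions = {
        "TS_only": ts - og - ge,
        "OG_only": og - ts - ge,
        "genome_only": ge - ts - og,
        "TS_OG": (ts & og) - ge,
        "TS_genome": (ts & ge) - og,
        "OG_genome": (og & ge) - ts,
        "TS_OG_genome": ts & og & ge,
    }
    return OverlapSummary(
        mclass, level,
        {name: len(keys) for name, keys in regions.items()},
        {name: sorted(keys) for name, keys in regions.items()},
    )


def colocated_candidates(genome_hotspots, ts_hotspots, og_hotspots,
                         gene_labels: dict) -> pd.DataFrame:
    """Novel proteins at genome-wide hotspots co-located with cancer hotspots.

    For each significant genome hotspot whose (family, column, class)
    matches a TS or OG hotspot, list the contributing proteins that are
    NOT already labelled TS/OG (or both), with the putative direction:
    gain-of-function for an OG match, loss-of-function for a TS match,
    ambiguous when both match.
    """
    ts_keys = {(t.family_id, t.msa_column, t.mclass) for t in ts_hotspots}
    og_keys = {(t.family_id, t.msa_column, t.mclass) for t in og_hotspots}
    rows = []
    for t in sorted(genome_hotspots,
                    key=lambda t: (t.family_id, t.msa_column, t.mclass)):
        key = (t.family_id, t.msa_column, t.mclass)
        in_ts, in_og = key in ts_keys, key in og_keys
        if not (in_ts or in_og):
            continue
        if in_ts and in_og:
            direction = "ambiguous"
        elif in_og:
            direction = "putative_gain_of_function"
        else:
            direction = "putative_loss_of_function"
        for protein in sorted(t.contributing_proteins):
            if gene_labels.get(protein, "other") in ("TS", "OG", "both"):
                continue
            rows.append([t.family_id, t.msa_column, t.mclass, protein,
                         direction, t.k, t.p_corrected])
    return pd.DataFrame(rows, columns=["family", "msa_column", "mclass",
                                       "protein", "direction", "k",
                                       "p_corrected"])


def overlap_frame(summary: OverlapSummary) -> pd.DataFrame:
    rows = []
    for region in REGIONS:
        items = summary.shared_items[region]
        rows.append([summary.mclass, summary.level, region,
                     summary.region_counts[region],
                     ";".join("|".join(map(str, k)) if isinstance(k, tuple)
                              else str(k) for k in items)])
    return pd.DataFrame(rows, columns=["mclass", "level", "region", "count",
                                       "items"])
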