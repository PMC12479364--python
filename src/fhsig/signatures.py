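"""Consensus signature derivation from multi-condition directional DE calls.

All rules are pure set logic on per-gene {-1, 0, +1} directional calls:

* **core** follicular-helper signature — same-direction calls in at least
  ``min_conditions`` of the per-infection T_FH-vs-T_eff contrasts *and* a
  same-direction call in the combined (all-infection) contrast;
* **regulatory (T_FR)** signature — condition-consensus calls agreeing in
  direction between the T_FR-vs-T_FH and T_FR-vs-T_eff contrast families;
* **pathogen-specific (context)** signatures — one-vs-rest calls per
  condition, split into genes shared between T_FH and T_eff, unique to T_FH,
  and unique to T_eff; the exported per-pathogen T_FH signature is
  shared + T_FH-unique.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping

import numpy as np
import pandas as pd

from .io import GeneSet, GeneSetCollection

DirectionCalls = pd.Series  # gene -> {-1, 0, +1}

__all__ = [
    "GeneSignature",
    "consensus_calls",
    "directional_intersections",
    "derive_core_signature",
    "derive_tfr_signature",
    "derive_context_signatures",
    "partition_core_groups",
    "annotate_signature",
    "zscore_matrix",
    "signatures_to_collection",
]


@dataclasses.dataclass
class GeneSignature:
    """Named up/down gene lists with a provenance record."""

    name: str
    up: frozenset[str]
    down: frozenset[str] = frozenset()
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        if self.up & self.down:
            raise ValueError(
                f"signature {self.name!r}: up and down sets overlap: "
                f"{sorted(self.up & self.down)[:5]}"
            )


def _check_universe(calls: Mapping[str, DirectionCalls]) -> pd.Index:
    items = list(calls.values())
    universe = items[0].index
    for s in items[1:]:
        if not s.index.equals(universe):
            raise ValueError("directional calls do not share one gene universe")
    return universe


def consensus_calls(
    per_condition: Mapping[str, DirectionCalls], min_conditions: int = 3
) -> DirectionCalls:
    """Directional consensus: the direction reached in >= min_conditions conditions.

    If neither direction reaches the quorum (or both do, with equal support),
    the consensus call is 0.
    """
    universe = _check_universe(per_condition)
    mat = pd.DataFrame({c: s for c, s in per_condition.items()})
    n_up = (mat == 1).sum(axis=1)
    n_down = (mat == -1).sum(axis=1)
    out = pd.Series(0, index=universe, dtype=int)
    out[(n_up >= min_conditions) & (n_up > n_down)] = 1
    out[(n_down >= min_conditions) & (n_down > n_up)] = -1
    return out


def directional_intersections(
    calls: Mapping[str, DirectionCalls],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene call table plus UpSet-style same-direction intersection counts.

    Counts tally, for every non-empty condition combination and direction,
    the genes called in exactly that combination (in that direction).
    """
    universe = _check_universe(calls)
    membership = pd.DataFrame({c: s for c, s in calls.items()}, index=universe)
    rows = []
    for direction, dval in [("up", 1), ("down", -1)]:
        hit = membership == dval
        combos = hit.apply(
            lambda r: ",".join(membership.columns[r.to_numpy()]), axis=1
        )
        for combo, group in combos[combos != ""].groupby(combos[combos != ""]):
            rows.append(
                {
                    "combination": combo,
                    "direction": direction,
                    "degree": combo.count(",") + 1,
                    "count": len(group),
                }
            )
    counts = pd.DataFrame(rows, columns=["combination", "direction", "degree", "count"])
    return membership, counts


def derive_core_signature(
    per_condition: Mapping[str, DirectionCalls],
    combined: DirectionCalls,
    min_conditions: int = 3,
) -> GeneSignature:
    """Core signature: same-direction quorum across conditions plus combined call."""
    if len(per_condition) < min_conditions:
        raise ValueError(
            f"need at least {min_conditions} conditions, got {len(per_condition)}"
        )
    universe = _check_universe(per_condition)
    if not combined.index.equals(universe):
        raise ValueError("combined calls do not share the per-condition gene universe")
    mat = pd.DataFrame({c: s for c, s in per_condition.items()})
    n_up = (mat == 1).sum(axis=1)
    n_down = (mat == -1).sum(axis=1)
    up = universe[(n_up >= min_conditions) & (combined == 1)]
    down = universe[(n_down >= min_conditions) & (combined == -1)]
    prov = {
        "rule": "core_consensus",
        "min_conditions": min_conditions,
        "conditions": list(per_condition),
        "condition_counts_up": n_up[up].to_dict(),
        "condition_counts_down": n_down[down].to_dict(),
    }
    return GeneSignature("core", frozenset(up), frozenset(down), prov)


def derive_tfr_signature(
    tfr_vs_tfh: Mapping[str, DirectionCalls],
    tfr_vs_teff: Mapping[str, DirectionCalls],
    min_conditions: int = 3,
) -> GeneSignature:
    """Regulatory signature: direction-consistent consensus in both contrast families."""
    if set(tfr_vs_tfh) != set(tfr_vs_teff):
        raise ValueError("the two contrast families must cover the same conditions")
    cons_tfh = consensus_calls(tfr_vs_tfh, min_conditions)
    cons_teff = consensus_calls(tfr_vs_teff, min_conditions)
    up = cons_tfh.index[(cons_tfh == 1) & (cons_teff == 1)]
    down = cons_tfh.index[(cons_tfh == -1) & (cons_teff == -1)]
    prov = {
        "rule": "tfr_dual_contrast_consensus",
        "min_conditions": min_conditions,
        "conditions": sorted(tfr_vs_tfh),
    }
    return GeneSignature("tfr", frozenset(up), frozenset(down), prov)


def derive_context_signatures(
    one_vs_rest_tfh: Mapping[str, DirectionCalls],
    one_vs_rest_teff: Mapping[str, DirectionCalls],
) -> dict[str, dict[str, GeneSignature]]:
    """Pathogen-specific signatures from one-vs-rest calls per condition.

    For each condition: ``shared`` (same direction in T_FH and T_eff),
    ``tfh_unique``, ``teff_unique``, and the exported ``tfh_specific`` =
    shared + tfh_unique.  A gene may appear in several conditions'
    signatures; provenance notes the multiplicity.
    """
    if set(one_vs_rest_tfh) != set(one_vs_rest_teff):
        raise ValueError("T_FH and T_eff one-vs-rest families must cover the same conditions")
    _check_universe({**one_vs_rest_tfh})
    out: dict[str, dict[str, GeneSignature]] = {}
    for cond in one_vs_rest_tfh:
        tfh = one_vs_rest_tfh[cond]
        teff = one_vs_rest_teff[cond]
        if not tfh.index.equals(teff.index):
            raise ValueError("gene universe mismatch between T_FH and T_eff calls")
        parts = {}
        for direction, d in [("up", 1), ("down", -1)]:
            both = tfh.index[(tfh == d) & (teff == d)]
            tfh_only = tfh.index[(tfh == d) & (teff == 0)]
            teff_only = tfh.index[(tfh == 0) & (teff == d)]
            parts[direction] = (set(both), set(tfh_only), set(teff_only))
        prov = {"rule": "one_vs_rest", "condition": cond}
        out[cond] = {
            "shared": GeneSignature(
                f"{cond}_shared", parts["up"][0], parts["down"][0], prov
            ),
            "tfh_unique": GeneSignature(
                f"{cond}_tfh_unique", parts["up"][1], parts["down"][1], prov
            ),
            "teff_unique": GeneSignature(
                f"{cond}_teff_unique", parts["up"][2], parts["down"][2], prov
            ),
            "tfh_specific": GeneSignature(
                f"{cond}_tfh_specific",
                parts["up"][0] | parts["up"][1],
                parts["down"][0] | parts["down"][1],
                prov,
            ),
        }
    return out


def partition_core_groups(
    core: GeneSignature, tfr_vs_teff_consensus: DirectionCalls
) -> pd.Series:
    """Four-group partition of core genes by T_FR co-expression.

    Group 1: core-up, not elevated in T_FR; group 2: core-up, co-expressed in
    T_FR; group 3: core-down, not elevated in T_FR; group 4: core-down but
    elevated in T_FR.
    """
    members = sorted(core.up | core.down)
    missing = [g for g in members if g not in tfr_vs_teff_consensus.index]
    if missing:
        raise ValueError(f"genes missing from T_FR calls: {missing[:10]}")
    groups = {}
    for g in core.up:
        groups[g] = 2 if tfr_vs_teff_consensus[g] == 1 else 1
    for g in core.down:
        groups[g] = 4 if tfr_vs_teff_consensus[g] == 1 else 3
    return pd.Series(groups, name="core_group").sort_index()


def annotate_signature(
    signature: GeneSignature, annotation_sets: GeneSetCollection
) -> pd.DataFrame:
    """Per-gene membership flags for each annotation set; unmatched genes = novel."""
    genes = sorted(signature.up | signature.down)
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    table["direction"] = ["up" if g in signature.up else "down" for g in genes]
    for s in annotation_sets:
        table[s.name] = [g in set(s.members) for g in genes]
    flag_cols = [s.name for s in annotation_sets]
    table["novel"] = (
        ~table[flag_cols].any(axis=1) if flag_cols else pd.Series(True, index=table.index)
    )
    return table


def zscore_matrix(
    logcpm: pd.DataFrame,
    genes: list[str] | pd.Index,
    group_by: pd.Series | None = None,
) -> pd.DataFrame:
    """Row z-scores of (optionally group-averaged) log-CPM for heatmap display.

    Sample-sd convention; zero-variance rows become all-zero.
    """
    missing = [g for g in genes if g not in logcpm.index]
    if missing:
        raise ValueError(f"genes absent from the expression matrix: {missing[:10]}")
    sub = logcpm.loc[list(genes)]
    if group_by is not None:
        sub = sub.T.groupby(group_by.reindex(sub.columns)).mean().T
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    z = sub.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z


def signatures_to_collection(
    signatures: Mapping[str, GeneSignature],
) -> GeneSetCollection:
    """Export signatures as a gene-set collection (``_up``/``_down`` suffixed)."""
    sets = []
    for sig in signatures.values():
        if sig.up:
            sets.append(GeneSet(f"{sig.name}_up", "derived signature", tuple(sorted(sig.up))))
        if sig.down:
            sets.append(
                GeneSet(f"{sig.name}_down", "derived signature", tuple(sorted(sig.down)))
            )
    return GeneSetCollection(sets)
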