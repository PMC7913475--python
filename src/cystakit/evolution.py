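"""Ancestral presence/absence reconstruction of cystatin gene types.

Formalizes verbal gain/loss hypotheses as parsimony reconstructions on a
rooted species tree: Fitch small parsimony (gains and losses equal cost),
Dollo parsimony (a single gain, any number of losses), and exhaustive
enumeration of alternative event histories ranked under a configurable gain
penalty (gains are rarer events than losses, default penalty 2).

The character is assumed absent on the stem below the root, so a history in
which the root itself carries the character includes one gain event on the
root's stem branch. ``fitch_min_changes`` follows the standard convention of
counting changes on tree branches only (no stem), so its count can sit one
below the cheapest gain+loss history when every optimal labeling places the
character at the root.

Branches are labeled by the clade below them: the tip name for pendant
branches, otherwise the sorted tip names joined by '+'.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from skbio import TreeNode

from .core_io import InputError, SpeciesTree


@dataclass
class ScenarioReconstruction:
    """A gain/loss event history for one character on a species tree."""

    character: str
    model: str  # fitch | dollo | gain_penalty(k)
    node_states: dict[str, int]
    events: list[tuple[str, str]]  # (branch label, 'gain'|'loss')
    n_gains: int
    n_losses: int
    cost: float

    def __post_init__(self) -> None:
        if self.model == "dollo" and self.n_gains > 1:
            raise ValueError("Dollo reconstruction cannot contain more than one gain")
        gains = sum(1 for _, kind in self.events if kind == "gain")
        losses = sum(1 for _, kind in self.events if kind == "loss")
        if (gains, losses) != (self.n_gains, self.n_losses):
            raise ValueError("event list inconsistent with gain/loss counts")

    @property
    def loss_branches(self) -> list[str]:
        return sorted(b for b, kind in self.events if kind == "loss")

    @property
    def gain_branches(self) -> list[str]:
        return sorted(b for b, kind in self.events if kind == "gain")


# ---------------------------------------------------------------------------
# tree helpers
# ---------------------------------------------------------------------------

def _as_root(tree: SpeciesTree | TreeNode) -> TreeNode:
    return tree.root if isinstance(tree, SpeciesTree) else tree


def _resolve_polytomies(root: TreeNode) -> TreeNode:
    """Fresh binary copy of the tree.

    Polytomies are nested left-to-right (deterministic); unary pass-through
    nodes (e.g., left by shearing) are collapsed with branch lengths summed.
    """

    def build(node: TreeNode) -> TreeNode:
        if node.is_tip():
            return TreeNode(name=node.name, length=node.length)
        kids = [build(ch) for ch in node.children]
        if len(kids) == 1:
            only = kids[0]
            if node.length is not None or only.length is not None:
                only.length = (node.length or 0.0) + (only.length or 0.0)
            return only
        while len(kids) > 2:
            merged = TreeNode(length=0.0, children=[kids[0], kids[1]])
            kids = [merged] + kids[2:]
        return TreeNode(name=node.name, length=node.length, children=kids)

    return build(root)


def _clade_label(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return "+".join(sorted(t.name for t in node.tips()))


def _tip_state(node: TreeNode, tip_states: Mapping[str, int]) -> int:
    lowered = {k.lower(): int(v) for k, v in tip_states.items()}
    if node.name.lower() not in lowered:
        raise InputError(f"tip {node.name!r} has no state")
    v = lowered[node.name.lower()]
    if v not in (0, 1):
        raise InputError(f"tip {node.name!r}: state must be 0 or 1, got {v}")
    return v


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def fitch_min_changes(
    tree: SpeciesTree | TreeNode, tip_states: Mapping[str, int]
) -> tuple[int, dict[str, int]]:
    """Standard two-pass small parsimony for a binary character.

    Returns the exact minimum number of state changes on tree branches and
    one optimal labeling (ties resolved toward state 0, root first).
    Polytomies are resolved deterministically before counting.
    """
    root = _resolve_polytomies(_as_root(tree))
    sets: dict[int, set[int]] = {}
    changes = 0
    for node in root.postorder():
        if node.is_tip():
            sets[id(node)] = {_tip_state(node, tip_states)}
        else:
            left, right = (sets[id(ch)] for ch in node.children)
            inter = left & right
            if inter:
                sets[id(node)] = inter
            else:
                sets[id(node)] = left | right
                changes += 1
    states: dict[str, int] = {}
    assigned: dict[int, int] = {}
    for node in root.preorder():
        options = sets[id(node)]
        if node.parent is None:
            state = min(options)
        else:
            parent_state = assigned[id(node.parent)]
            state = parent_state if parent_state in options else min(options)
        assigned[id(node)] = state
        states[_clade_label(node)] = state
    return changes, states


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------

def dollo_reconstruction(
    tree: SpeciesTree | TreeNode,
    tip_states: Mapping[str, int],
    character: str = "",
) -> ScenarioReconstruction:
    """Single-gain reconstruction: one gain above the MRCA of all present
    tips, then the minimum number of losses below it.

    With no present tip the result is the degenerate no-gain history.
    """
    root = _resolve_polytomies(_as_root(tree))
    present = [t for t in root.tips() if _tip_state(t, tip_states) == 1]
    node_states: dict[str, int] = {}
    events: list[tuple[str, str]] = []
    if not present:
        for node in root.traverse():
            node_states[_clade_label(node)] = 0
        return ScenarioReconstruction(
            character=character, model="dollo", node_states=node_states,
            events=[], n_gains=0, n_losses=0, cost=0.0,
        )
    mrca = present[0] if len(present) == 1 else root.lca([t.name for t in present])
    inside = set()
    for t in present:
        node = t
        while node is not None:
            inside.add(id(node))
            if node is mrca:
                break
            node = node.parent
    # states: 1 on every branch of the path system from the MRCA to present
    # tips; losses on the maximal subtrees below the MRCA holding no present tip
    def walk(node: TreeNode) -> None:
        state = 1 if id(node) in inside else 0
        node_states[_clade_label(node)] = state
        if state == 0:
            events.append((_clade_label(node), "loss"))
            for sub in node.traverse():
                node_states[_clade_label(sub)] = 0
            return
        for ch in node.children:
            walk(ch)

    # everything outside the MRCA clade is 0 (the gain happens on its stem)
    for node in root.traverse():
        node_states.setdefault(_clade_label(node), 0)
    events.append((_clade_label(mrca), "gain"))
    walk(mrca)
    node_states[_clade_label(mrca)] = 1
    events_sorted = sorted(events, key=lambda e: (e[1] != "gain", e[0]))
    n_losses = sum(1 for _, k in events_sorted if k == "loss")
    return ScenarioReconstruction(
        character=character, model="dollo", node_states=node_states,
        events=events_sorted, n_gains=1, n_losses=n_losses,
        cost=float(1 + n_losses),
    )


# ---------------------------------------------------------------------------
# scenario enumeration
# ---------------------------------------------------------------------------

def enumerate_scenarios(
    tree: SpeciesTree | TreeNode,
    tip_states: Mapping[str, int],
    max_gains: int = 3,
    gain_penalty: float = 2.0,
    character: str = "",
) -> list[ScenarioReconstruction]:
    """All event histories with at most ``max_gains`` gains and, for each
    gain count, the minimum number of losses; ranked by
    ``gain_penalty * n_gains + n_losses``.

    Ties are broken by fewer total events, then lexicographic branch order.
    Exhaustive over internal labelings, so intended for lineage-level trees
    (tens of tips).
    """
    if max_gains < 1:
        raise InputError("max_gains must be at least 1")
    root = _resolve_polytomies(_as_root(tree))
    internal = [n for n in root.postorder() if not n.is_tip()]
    tips = list(root.tips())
    tip_state_by_id = {id(t): _tip_state(t, tip_states) for t in tips}

    best_by_gain: dict[int, list[ScenarioReconstruction]] = {}
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        states = dict(zip((id(n) for n in internal), assignment))
        states.update(tip_state_by_id)
        events: list[tuple[str, str]] = []
        root_state = states[id(root)]
        if root_state == 1:
            events.append((_clade_label(root), "gain"))  # origin on the stem
        for node in root.preorder():
            if node.parent is None:
                continue
            a, b = states[id(node.parent)], states[id(node)]
            if a == 0 and b == 1:
                events.append((_clade_label(node), "gain"))
            elif a == 1 and b == 0:
                events.append((_clade_label(node), "loss"))
        n_gains = sum(1 for _, k in events if k == "gain")
        n_losses = len(events) - n_gains
        if n_gains == 0 or n_gains > max_gains:
            if not (n_gains == 0 and all(v == 0 for v in tip_state_by_id.values())):
                continue
        rec = ScenarioReconstruction(
            character=character,
            model=f"gain_penalty({gain_penalty:g})",
            node_states={_clade_label(n): states[id(n)] for n in root.traverse()},
            events=sorted(events, key=lambda e: (e[1] != "gain", e[0])),
            n_gains=n_gains,
            n_losses=n_losses,
            cost=gain_penalty * n_gains + n_losses,
        )
        bucket = best_by_gain.setdefault(n_gains, [])
        if not bucket or n_losses < bucket[0].n_losses:
            best_by_gain[n_gains] = [rec]
        elif n_losses == bucket[0].n_losses:
            bucket.append(rec)

    out = [r for bucket in best_by_gain.values() for r in bucket]
    out.sort(key=lambda r: (r.cost, r.n_gains + r.n_losses, [b for b, _ in r.events]))
    return out


def scenarios_table(scenarios: Sequence[ScenarioReconstruction]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "rank": i,
                "model": s.model,
                "n_gains": s.n_gains,
                "n_losses": s.n_losses,
                "cost": s.cost,
                "gain_branches": ";".join(s.gain_branches),
                "loss_branches": ";".join(s.loss_branches),
            }
            for i, s in enumerate(scenarios)
        ],
        columns=["rank", "model", "n_gains", "n_losses", "cost", "gain_branches", "loss_branches"],
    )


def annotated_newick(
    tree: SpeciesTree | TreeNode, reconstruction: ScenarioReconstruction
) -> str:
    """Newick string with internal nodes labeled ``state<0|1>``."""
    root = _resolve_polytomies(_as_root(tree))
    for node in root.traverse():
        state = reconstruction.node_states.get(_clade_label(node))
        if not node.is_tip() and state is not None:
            node.name = f"state{state}"
    return str(root).strip()
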