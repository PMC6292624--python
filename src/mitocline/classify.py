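"""Hierarchical haplogroup assignment from defining SNPs.

Each sample is classified by greedy root-to-leaf descent through a
panel-bound :class:`~mitocline.tree.HaploTree`: at every step, among the
current node's *callable* children (those with at least one panel-typed
defining variant), the child maximizing the matched fraction of its observed
defining variants is accepted, provided enough variants were observed and the
matched fraction meets the level's acceptance floor. Descent stops when no
child qualifies; the deepest accepted node at each level (macro, haplogroup,
sub-haplogroup) is reported.

Acceptance is strict at the macro level (all observed defining variants must
match) and lenient below (half), a reproducible surrogate for the manual
"unequivocal" matching used in the published survey, whose exact criterion is
unstated. Ties between equally scoring children break on higher matched
count, then lexicographically smaller name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ALT, MISSING, GenotypeMatrix
from .tree import HaploTree, LEVELS

__all__ = [
    "UNASSIGNED",
    "ClassifierRule",
    "HgCall",
    "score_node",
    "classify_sample",
    "classify_cohort",
    "calls_to_frame",
]

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class ClassifierRule:
    """Acceptance rule for greedy descent.

    min_observed: minimum non-missing defining variants needed to judge a node.
    min_match_frac_macro / min_match_frac: matched/observed floor at the macro
        level and below, respectively.
    cumulative: score candidates on the cumulative root-to-candidate defining
        set instead of the candidate's own set (penalizes back-mutations).
    """

    min_observed: int = 1
    min_match_frac_macro: float = 1.0
    min_match_frac: float = 0.5
    cumulative: bool = False

    def frac_for(self, level: str) -> float:
        return self.min_match_frac_macro if level == "macro" else self.min_match_frac


@dataclass
class HgCall:
    """Per-sample classification with per-level diagnostics."""

    sample_id: str
    macro_hg: str = UNASSIGNED
    hg: str = UNASSIGNED
    sub_hg: str = UNASSIGNED
    diagnostics: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    status: str = "unassigned"

    def label_at(self, level: str) -> str:
        return {"macro": self.macro_hg, "hg": self.hg, "subhg": self.sub_hg}[level]

    @property
    def deepest(self) -> str:
        for label in (self.sub_hg, self.hg, self.macro_hg):
            if label != UNASSIGNED:
                return label
        return UNASSIGNED


def score_node(genotype: np.ndarray, node) -> tuple[int, int, int]:
    """(observed, matched, mismatched) over a node's panel-covered variants."""
    if node.covered_idx is None:
        raise ValueError(f"node {node.name} has no panel attached")
    if not node.covered_idx:
        return (0, 0, 0)
    sub = genotype[list(node.covered_idx)]
    observed = int((sub != MISSING).sum())
    matched = int((sub == ALT).sum())
    return observed, matched, observed - matched


def _path_cov(tree: HaploTree, name: str) -> list[int]:
    cols: list[int] = []
    for node_name in tree.path_to(name):
        cols.extend(tree.nodes[node_name].covered_idx or ())
    return cols


def classify_sample(
    genotype: np.ndarray,
    tree: HaploTree,
    rule: ClassifierRule = ClassifierRule(),
    sample_id: str = "",
) -> HgCall:
    """Greedy root-to-leaf descent for one sample's call vector."""
    call = HgCall(sample_id=sample_id)
    cur = tree.root
    accepted: list[str] = []
    while True:
        best = None  # (frac, matched, -ordinal) maximized
        best_key = None
        for child in tree.nodes[cur].children:
            node = tree.nodes[child]
            if not node.callable_:
                continue
            if rule.cumulative:
                idx = _path_cov(tree, child)
                sub = genotype[idx]
                obs = int((sub != MISSING).sum())
                matched = int((sub == ALT).sum())
            else:
                obs, matched, _ = score_node(genotype, node)
            if obs < rule.min_observed:
                continue
            frac = matched / obs
            if frac < rule.frac_for(node.level):
                continue
            key = (frac, matched, _NameOrder(child))
            if best_key is None or key > best_key:
                best, best_key = child, key
        if best is None:
            break
        accepted.append(best)
        node = tree.nodes[best]
        obs, matched, mism = score_node(genotype, node)
        call.diagnostics[node.level] = (obs, matched, mism)
        cur = best

    for name in accepted:
        level = tree.nodes[name].level
        if level == "macro":
            call.macro_hg = name
        elif level == "hg":
            call.hg = name
        elif level == "subhg":
            call.sub_hg = name

    if not accepted:
        call.status = "unassigned"
    else:
        deepest = accepted[-1]
        has_callable_child = any(
            tree.nodes[c].callable_ for c in tree.nodes[deepest].children
        )
        call.status = (
            "full" if call.sub_hg != UNASSIGNED or not has_callable_child else "partial"
        )
    return call


class _NameOrder(str):
    """Reverses string comparison so lexicographically smaller names win ties."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def classify_cohort(
    g: GenotypeMatrix,
    tree: HaploTree,
    rule: ClassifierRule = ClassifierRule(),
) -> tuple[list[HgCall], pd.Series]:
    """Classify every sample; also report the unassigned fraction per level.

    Uses vectorized per-node scoring over all samples, then runs the same
    greedy descent as :func:`classify_sample` on the precomputed scores.
    """
    n = g.n_samples
    if n == 0:
        return [], pd.Series({lv: 0.0 for lv in LEVELS}, name="unassigned_fraction")
    calls = g.calls
    obs_a: dict[str, np.ndarray] = {}
    match_a: dict[str, np.ndarray] = {}
    for name, node in tree.nodes.items():
        idx = list(node.covered_idx or ())
        if rule.cumulative and node.parent is not None:
            idx = _path_cov(tree, name)
        if not idx:
            obs_a[name] = np.zeros(n, dtype=np.int32)
            match_a[name] = np.zeros(n, dtype=np.int32)
            continue
        sub = calls[:, idx]
        obs_a[name] = (sub != MISSING).sum(axis=1).astype(np.int32)
        match_a[name] = (sub == ALT).sum(axis=1).astype(np.int32)

    own_score: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if rule.cumulative:
        for name, node in tree.nodes.items():
            idx = list(node.covered_idx or ())
            if idx:
                sub = calls[:, idx]
                own_score[name] = (
                    (sub != MISSING).sum(axis=1),
                    (sub == ALT).sum(axis=1),
                )
            else:
                z = np.zeros(n, dtype=np.int32)
                own_score[name] = (z, z)

    out: list[HgCall] = []
    for i in range(n):
        call = HgCall(sample_id=g.sample_ids[i])
        cur = tree.root
        accepted: list[str] = []
        while True:
            best, best_key = None, None
            for child in tree.nodes[cur].children:
                node = tree.nodes[child]
                if not node.callable_:
                    continue
                obs = int(obs_a[child][i])
                matched = int(match_a[child][i])
                if obs < rule.min_observed:
                    continue
                frac = matched / obs
                if frac < rule.frac_for(node.level):
                    continue
                key = (frac, matched, _NameOrder(child))
                if best_key is None or key > best_key:
                    best, best_key = child, key
            if best is None:
                break
            accepted.append(best)
            node = tree.nodes[best]
            if rule.cumulative:
                o, m = own_score[best]
                obs, matched = int(o[i]), int(m[i])
            else:
                obs, matched = int(obs_a[best][i]), int(match_a[best][i])
            call.diagnostics[node.level] = (obs, matched, obs - matched)
            cur = best
        for name in accepted:
            level = tree.nodes[name].level
            if level == "macro":
                call.macro_hg = name
            elif level == "hg":
                call.hg = name
            else:
                call.sub_hg = name
        if not accepted:
            call.status = "unassigned"
        else:
            deepest = accepted[-1]
            has_child = any(
                tree.nodes[c].callable_ for c in tree.nodes[deepest].children
            )
            call.status = (
                "full"
                if call.sub_hg != UNASSIGNED or not has_child
                else "partial"
            )
        out.append(call)

    summary = pd.Series(
        {
            "macro": float(np.mean([c.macro_hg == UNASSIGNED for c in out])),
            "hg": float(np.mean([c.hg == UNASSIGNED for c in out])),
            "subhg": float(np.mean([c.sub_hg == UNASSIGNED for c in out])),
        },
        name="unassigned_fraction",
    )
    return out, summary


def calls_to_frame(calls: list[HgCall]) -> pd.DataFrame:
    """Flat table of classifications (one row per sample)."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "macro_hg": [c.macro_hg for c in calls],
            "hg": [c.hg for c in calls],
            "sub_hg": [c.sub_hg for c in calls],
            "status": [c.status for c in calls],
        }
    )
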