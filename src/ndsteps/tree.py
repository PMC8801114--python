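"""The genealogy tree: shared (trunk) vs. disease-specific (branch) steps.

Diseases whose onset requires n sequential steps may share early steps.
Sharing is constrained by parsimony: a step keeps its ordinal number in
every disease it is shared by (a disease with n steps can share ordinals
1..n only), and among the admissible combinations the one maximizing the
total number of shared steps is chosen.  Because the shared sets along
the trunk must be nested (the tree has a single trunk with branch-offs),
a sharing scheme is fully determined by the set C of co-sharing diseases:
the set sharing ordinal k is S_k = {d in C : n_d >= k}, automatically a
decreasing chain.  Which diseases may co-share at all is an injectable
pairwise compatibility predicate (complete by default).

A disease's common steps are the ordinals it shares with at least one
other disease; the remainder are its specific steps, drawn as a branch
leaving the trunk at height = common steps.  The extended tree gives the
trunk, at each branch point, a width equal to the mean years/step of the
diseases branching there.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .age_range import AgeRangeSummary

Compatibility = Callable[[str, str], bool]


def _fully_compatible(a: str, b: str) -> bool:
    return True


def _is_clique(labels: Sequence[str], compatible: Compatibility) -> bool:
    return all(compatible(a, b) and compatible(b, a) for a, b in itertools.combinations(labels, 2))


@dataclasses.dataclass(frozen=True)
class SharingMatrix:
    """Candidate sharing combinations per step ordinal.

    ``diseases``: ordered (label, n_steps) pairs.  ``candidates[k]`` lists
    the subsets (tuples of labels) that could share step ordinal k: every
    member has at least k steps and the subset is pairwise compatible.
    Subsets are ordered by size descending, then lexicographically.
    """

    diseases: tuple[tuple[str, int], ...]
    candidates: dict[int, tuple[tuple[str, ...], ...]]

    @property
    def n_steps_by_label(self) -> dict[str, int]:
        return dict(self.diseases)

    @property
    def max_ordinal(self) -> int:
        return max((n for _, n in self.diseases), default=0)


def build_sharing_matrix(
    allocatable: Sequence[tuple[str, int]],
    compatibility: Compatibility | None = None,
) -> SharingMatrix:
    """Enumerate, per ordinal, the feasible sharing subsets.

    A subset is feasible at ordinal k iff every member has >= k steps and
    all pairs are compatible.  Labels must be unique; step counts >= 1.
    """
    labels = [lab for lab, _ in allocatable]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate disease labels")
    if any(n < 1 for _, n in allocatable):
        raise ValueError("step counts must be >= 1")
    if len(allocatable) > 16:
        raise ValueError("subset enumeration limited to 16 diseases")
    compatible = compatibility or _fully_compatible
    diseases = tuple(sorted(allocatable))
    nmap = dict(diseases)
    max_n = max((n for _, n in diseases), default=0)

    # feasible cliques among all diseases, reused per ordinal
    cliques: list[tuple[str, ...]] = []
    names = [lab for lab, _ in diseases]
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            if _is_clique(combo, compatible):
                cliques.append(combo)

    candidates: dict[int, tuple[tuple[str, ...], ...]] = {}
    for k in range(1, max_n + 1):
        feasible = [c for c in cliques if all(nmap[lab] >= k for lab in c)]
        feasible.sort(key=lambda c: (-len(c), c))
        candidates[k] = tuple(feasible)
    return SharingMatrix(diseases=diseases, candidates=candidates)


@dataclasses.dataclass(frozen=True)
class StepAllocation:
    """Split of one disease's steps into common (trunk) and specific."""

    label: str
    n_steps: int
    common_steps: int
    specific_steps: int

    def __post_init__(self) -> None:
        assert self.common_steps + self.specific_steps == self.n_steps
        assert self.common_steps >= 0

    @property
    def branch_height(self) -> int:
        return self.common_steps


@dataclasses.dataclass(frozen=True)
class AllocationResult:
    """Allocations plus the selected sharing chain.

    ``shared_sets[k]`` is the set of diseases sharing ordinal k (only
    ordinals shared by >= 2 diseases appear); the sets form a decreasing
    chain.  ``promoters[k]`` attributes each shared ordinal once, to the
    first disease (in label order) of its sharing set.  ``objective`` is
    the total number of (disease, ordinal) sharing incidences.
    """

    allocations: tuple[StepAllocation, ...]
    shared_sets: dict[int, tuple[str, ...]]
    promoters: dict[int, str]
    objective: int

    def __iter__(self):
        return iter(self.allocations)

    def by_label(self) -> dict[str, StepAllocation]:
        return {a.label: a for a in self.allocations}


def _chain_objective(ns: Sequence[int]) -> int:
    """Total sharing incidences for a co-sharing set with step counts ns."""
    total = 0
    for k in itertools.count(1):
        cnt = sum(1 for n in ns if n >= k)
        if cnt < 2:
            break
        total += cnt
    return total


def _preference_key(subset: tuple[str, ...], nmap: Mapping[str, int]):
    """Tie-break: prefer larger step counts, then lexicographic labels.

    Returns a key where larger is better for the step-count part and
    smaller is better for the label part; callers compare via max on
    (objective, steps_desc, negated-label preference) — implemented here
    as (steps_desc, inverted labels) with labels inverted by taking the
    negative of their ordinals is messy, so we return a tuple usable with
    ``min`` on the label part separately.
    """
    steps_desc = tuple(sorted((nmap[lab] for lab in subset), reverse=True))
    return steps_desc, subset


def _better(
    cand: tuple[int, tuple[int, ...], tuple[str, ...]],
    best: tuple[int, tuple[int, ...], tuple[str, ...]] | None,
) -> bool:
    """Compare (objective, steps_desc, labels): higher objective wins,
    then larger step counts, then lexicographically smaller label tuple."""
    if best is None:
        return True
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] > best[1]
    return cand[2] < best[2]


def _result_from_set(
    chosen: tuple[str, ...], nmap: Mapping[str, int], objective: int
) -> AllocationResult:
    shared_sets: dict[int, tuple[str, ...]] = {}
    promoters: dict[int, str] = {}
    K = 0
    for k in itertools.count(1):
        members = tuple(sorted(lab for lab in chosen if nmap[lab] >= k))
        if len(members) < 2:
            break
        shared_sets[k] = members
        promoters[k] = members[0]
        K = k
    allocations = []
    for lab in sorted(nmap):
        n = nmap[lab]
        common = min(n, K) if lab in chosen and K > 0 else 0
        allocations.append(
            StepAllocation(
                label=lab, n_steps=n, common_steps=common, specific_steps=n - common
            )
        )
    return AllocationResult(
        allocations=tuple(allocations),
        shared_sets=shared_sets,
        promoters=promoters,
        objective=objective,
    )


def allocate_steps(sharing: SharingMatrix) -> AllocationResult:
    """Choose the sharing scheme maximizing the total shared steps.

    Exact search: every nested chain is generated by a pairwise-compatible
    co-sharing set C (the ordinal-1 candidates), with S_k = {d in C :
    n_d >= k}; the best C under the objective (then the tie-breaks:
    larger step counts, lexicographic) is selected.  With complete
    compatibility this coincides with picking, at each ordinal, the
    largest feasible subset nested in the previous one.
    """
    nmap = sharing.n_steps_by_label
    best: tuple[int, tuple[int, ...], tuple[str, ...]] | None = None
    for subset in sharing.candidates.get(1, ()):
        obj = _chain_objective([nmap[lab] for lab in subset])
        steps_desc, labels = _preference_key(subset, nmap)
        cand = (obj, steps_desc, labels)
        if _better(cand, best):
            best = cand
    if best is None or best[0] == 0:
        return _result_from_set((), nmap, 0)
    return _result_from_set(best[2], nmap, best[0])


def brute_force_allocate(
    allocatable: Sequence[tuple[str, int]],
    compatibility: Compatibility | None = None,
) -> AllocationResult:
    """Exhaustive oracle for small instances (<= 5 diseases, <= 13 steps).

    Enumerates every subset of diseases as the co-sharing set, checks
    pairwise compatibility directly, scores it by counting, ordinal by
    ordinal, the diseases still sharing, and keeps the best under the
    same tie-breaks as :func:`allocate_steps`.  Test-oracle use only.
    """
    if len(allocatable) > 5 or any(n > 13 for _, n in allocatable):
        raise ValueError("brute force bounded to <= 5 diseases and <= 13 steps")
    compatible = compatibility or _fully_compatible
    nmap = dict(sorted(allocatable))
    names = sorted(nmap)
    best: tuple[int, tuple[int, ...], tuple[str, ...]] | None = None
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            if not _is_clique(subset, compatible):
                continue
            obj = 0
            for k in range(1, 14):
                cnt = sum(1 for lab in subset if nmap[lab] >= k)
                if cnt >= 2:
                    obj += cnt
            steps_desc = tuple(sorted((nmap[lab] for lab in subset), reverse=True))
            cand = (obj, steps_desc, subset)
            if _better(cand, best):
                best = cand
    assert best is not None
    if best[0] == 0:
        return _result_from_set((), nmap, 0)
    return _result_from_set(best[2], nmap, best[0])


TIER_STEM = "stem"
TIER_TRUNK = "trunk_level"
TIER_CROWN = "crown"
TIER_UNCLASSIFIED = "unclassified"


def classify_tiers(n_steps_by_label: Mapping[str, int]) -> dict[str, str]:
    """Tier of each disease by step count.

    Stem: fewer than 3 steps; trunk-level: 5-7 steps; crown: more than 7.
    Counts of 3 or 4 fall between the bands and are left unclassified.
    """
    out = {}
    for lab, n in n_steps_by_label.items():
        if n < 3:
            out[lab] = TIER_STEM
        elif 5 <= n <= 7:
            out[lab] = TIER_TRUNK
        elif n > 7:
            out[lab] = TIER_CROWN
        else:
            out[lab] = TIER_UNCLASSIFIED
    return out


@dataclasses.dataclass(frozen=True)
class BranchPoint:
    """Diseases leaving the trunk at one height, with the trunk width there."""

    height: int
    diseases: tuple[str, ...]
    trunk_width: float  # mean years/step of the diseases branching here


@dataclasses.dataclass(frozen=True)
class GenealogyTree:
    """The extended genealogy tree.

    ``trunk``: ordinal -> sharing set along the common trunk.
    ``branch_points``: one per distinct branch height (common-step count),
    ascending, each carrying the trunk width (mean years/step of the
    diseases branching there).  ``branches``: per-disease specific-step
    chain lengths.  ``sides``: left/right/center placement (male/female/
    pooled).  ``reference_leaves``: strata outside the multistep model
    (failed the linearity gate), drawn beside the tree, not on the trunk.
    """

    trunk: dict[int, tuple[str, ...]]
    branch_points: tuple[BranchPoint, ...]
    branches: dict[str, int]
    tiers: dict[str, str]
    years_per_step: dict[str, float]
    sides: dict[str, str]
    reference_leaves: tuple[str, ...]

    @property
    def trunk_height(self) -> int:
        return max(self.trunk, default=0)

    def to_dict(self) -> dict:
        return {
            "trunk": {str(k): list(v) for k, v in sorted(self.trunk.items())},
            "branch_points": [
                {
                    "height": bp.height,
                    "diseases": list(bp.diseases),
                    "trunk_width": bp.trunk_width,
                }
                for bp in self.branch_points
            ],
            "branches": dict(sorted(self.branches.items())),
            "tiers": dict(sorted(self.tiers.items())),
            "years_per_step": dict(sorted(self.years_per_step.items())),
            "sides": dict(sorted(self.sides.items())),
            "reference_leaves": list(self.reference_leaves),
        }

    def to_json(self, path: str | Path, **meta) -> Path:
        path = Path(path)
        payload = {**meta, "tree": self.to_dict()}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def build_tree(
    result: AllocationResult,
    summaries: Sequence[AgeRangeSummary],
    sex_mode: str = "pooled",
) -> GenealogyTree:
    """Assemble the extended tree from allocations and years/step summaries.

    Every allocated disease must have a years/step value; diseases whose
    summaries failed the linearity gate become reference leaves.  In
    ``split`` mode male strata are placed on the left side, female on the
    right; in ``pooled`` mode everything is centered.
    """
    if sex_mode not in ("pooled", "split"):
        raise ValueError("sex_mode must be 'pooled' or 'split'")
    by_label = {s.label: s for s in summaries}
    yps: dict[str, float] = {}
    for alloc in result.allocations:
        s = by_label.get(alloc.label)
        if s is None or s.years_per_step is None:
            raise ValueError(f"no years/step summary for allocated stratum {alloc.label}")
        yps[alloc.label] = s.years_per_step

    points: dict[int, list[str]] = {}
    for alloc in result.allocations:
        points.setdefault(alloc.common_steps, []).append(alloc.label)
    branch_points = tuple(
        BranchPoint(
            height=h,
            diseases=tuple(sorted(labs)),
            trunk_width=sum(yps[lab] for lab in labs) / len(labs),
        )
        for h, labs in sorted(points.items())
    )
    sides = {}
    for alloc in result.allocations:
        if sex_mode == "split":
            sides[alloc.label] = "left" if alloc.label.endswith("m") else (
                "right" if alloc.label.endswith("f") else "center"
            )
        else:
            sides[alloc.label] = "center"
    reference = tuple(
        sorted(
            s.label
            for s in summaries
            if s.label not in {a.label for a in result.allocations}
        )
    )
    return GenealogyTree(
        trunk=dict(result.shared_sets),
        branch_points=branch_points,
        branches={a.label: a.specific_steps for a in result.allocations},
        tiers=classify_tiers({a.label: a.n_steps for a in result.allocations}),
        years_per_step=yps,
        sides=sides,
        reference_leaves=reference,
    )


def allocations_to_frame(result: AllocationResult):
    """Tabulate allocations (one row per disease)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "stratum": a.label,
                "n_steps": a.n_steps,
                "common_steps": a.common_steps,
                "specific_steps": a.specific_steps,
            }
            for a in result.allocations
        ]
    )


def plot_tree(tree: GenealogyTree, path) -> Path:
    """Render the extended tree: trunk height = common steps, trunk width
    at each branch point = mean years/step of the diseases leaving there,
    branches = specific-step chains."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    prev_h = 0.0
    for bp in tree.branch_points:
        if bp.height > 0:
            half = bp.trunk_width / 2.0
            ax.fill_betweenx(
                [prev_h, bp.height], -half, half, color="saddlebrown", alpha=0.6
            )
            prev_h = float(bp.height)
        n = len(bp.diseases)
        for i, lab in enumerate(bp.diseases):
            side = tree.sides.get(lab, "center")
            direction = -1.0 if side == "left" else 1.0 if side == "right" else (
                -1.0 if i % 2 else 1.0
            )
            x0 = direction * bp.trunk_width / 2.0
            x1 = direction * (bp.trunk_width / 2.0 + 2.0 + i)
            top = bp.height + tree.branches.get(lab, 0)
            ax.plot([x0, x1, x1], [bp.height, bp.height, top], color="forestgreen")
            ax.annotate(
                f"{lab} (n={bp.height + tree.branches.get(lab, 0)})",
                (x1, top),
                fontsize=7,
                ha="center",
                va="bottom",
            )
    for j, lab in enumerate(tree.reference_leaves):
        ax.annotate(f"{lab} (reference)", (0, -1.5 - j), fontsize=7, ha="center")
    ax.set_ylabel("steps (trunk height = common steps)")
    ax.set_xlabel("years/step (trunk width at branch point)")
    ax.set_title("Extended genealogy tree")
    ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
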