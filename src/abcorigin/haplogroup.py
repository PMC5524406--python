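"""Hierarchical Y-haplogroup assignment and frequency tabulation.

A sample's haplogroup is the deepest node of a rooted marker tree whose
root path is supported by its binary genotype.  The rules, in order:

* a branch is *supported* when at least one of its defining markers is
  called derived, and *contradicted* when any of them is called ancestral;
* a node is *attainable* when its own branch is supported, no branch on its
  root path is contradicted, and every unsupported branch on the path is
  merely missing (derived calls below imply derived state above);
* the assignment is the deepest attainable node (ties broken by tree
  preorder); the root when nothing is attainable;
* the conflict flag is raised when the genotype also supports a branch
  incompatible with the assignment — either a supported branch off the
  chosen root path, or a supported branch sitting below an explicitly
  contradicted one.

Markers present in the genotype but absent from the tree are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .formats_io import (
    ANCESTRAL,
    DERIVED,
    CrossRefError,
    HaplogroupTree,
    MarkerPanel,
)


@dataclass
class Assignment:
    """Result of placing one sample on the haplogroup tree."""

    sample_id: str
    haplogroup: str
    path: list[str]          # derived-implied nodes, root -> haplogroup
    conflict: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        flag = " (conflict)" if self.conflict else ""
        return f"{self.sample_id}: {self.haplogroup}{flag}"


def _branch_states(profile: dict[str, int], tree: HaplogroupTree):
    """Per-node (supported, contradicted) given one marker->call profile."""
    supported: set[str] = set()
    contradicted: set[str] = set()
    node_of = tree.marker_to_node()
    for marker, call in profile.items():
        node = node_of.get(marker)
        if node is None:
            continue  # genotyped marker not on the tree: ignorable extra
        if call == DERIVED:
            supported.add(node)
        elif call == ANCESTRAL:
            contradicted.add(node)
    return supported, contradicted


def _attainable(name: str, tree: HaplogroupTree,
                supported: set[str], contradicted: set[str]) -> bool:
    if name == tree.root:
        return True
    path = tree.path_to_root(name)[1:]  # skip root, which owns no branch
    if any(b in contradicted for b in path):
        return False
    return path[-1] in supported


def assign_haplogroup(profile: dict[str, int], tree: HaplogroupTree,
                      sample_id: str = "") -> Assignment:
    """Assign one binary-marker profile to its deepest supported haplogroup.

    ``profile`` maps marker name to call (``DERIVED``/``ANCESTRAL``);
    missing markers are simply absent from the mapping.
    """
    supported, contradicted = _branch_states(profile, tree)

    best = tree.root
    best_depth = 0
    for name in tree.names_in_preorder():
        depth = tree.depth(name)
        if depth > best_depth and _attainable(name, tree, supported, contradicted):
            best, best_depth = name, depth

    chosen_path = set(tree.path_to_root(best))
    conflict = False
    for node in supported:
        if node not in chosen_path:
            # a derived call that the chosen placement cannot explain:
            # either an incompatible branch, or a branch below an
            # explicitly contradicted ancestor
            conflict = True
            break

    return Assignment(
        sample_id=sample_id,
        haplogroup=best,
        path=tree.path_to_root(best),
        conflict=conflict,
    )


def assign_panel(panel: MarkerPanel, tree: HaplogroupTree) -> list[Assignment]:
    """Assign every sample of a panel; per-sample conflicts become flags,
    never exceptions."""
    return [
        assign_haplogroup(panel.profile(i), tree, sample_id=panel.sample_ids[i])
        for i in range(panel.n_samples)
    ]


def haplogroup_frequencies(assignments: list[Assignment],
                           populations: list[str],
                           haplogroup_order: list[str] | None = None,
                           ) -> pd.DataFrame:
    """Per-population haplogroup frequency table in percent.

    Rows are populations (first-appearance order), columns haplogroups; each
    row sums to exactly 100 before any rounding.  Counts are recoverable as
    ``freq * N / 100``.
    """
    if len(assignments) != len(populations):
        raise CrossRefError("assignments and population labels must align")
    pop_order = list(dict.fromkeys(populations))
    if haplogroup_order is None:
        haplogroup_order = sorted({a.haplogroup for a in assignments})
    counts = pd.DataFrame(0, index=pop_order, columns=haplogroup_order,
                          dtype=float)
    for a, pop in zip(assignments, populations):
        if pop not in counts.index:
            raise CrossRefError(f"unknown population label {pop!r}")
        if a.haplogroup not in counts.columns:
            raise CrossRefError(
                f"haplogroup {a.haplogroup!r} not in requested column order"
            )
        counts.loc[pop, a.haplogroup] += 1
    n_per_pop = counts.sum(axis=1)
    if (n_per_pop == 0).any():
        empty = list(n_per_pop.index[n_per_pop == 0])
        raise CrossRefError(f"populations without samples: {empty}")
    freqs = counts.div(n_per_pop, axis=0) * 100.0
    freqs.insert(0, "N", n_per_pop.astype(int))
    return freqs


def write_frequency_table(freqs: pd.DataFrame, path) -> None:
    """Render the frequency table to TSV with one-decimal percentages."""
    out = freqs.copy()
    pct_cols = [c for c in out.columns if c != "N"]
    out[pct_cols] = out[pct_cols].round(1)
    out.to_csv(path, sep="\t", index_label="population")


def write_assignments(assignments: list[Assignment], populations: list[str],
                      path) -> None:
    pd.DataFrame({
        "sample_id": [a.sample_id for a in assignments],
        "population": populations,
        "haplogroup": [a.haplogroup for a in assignments],
        "path": ["/".join(a.path) for a in assignments],
        "conflict": [int(a.conflict) for a in assignments],
    }).to_csv(path, sep="\t", index=False)


__all__ = [
    "Assignment",
    "assign_haplogroup",
    "assign_panel",
    "haplogroup_frequencies",
    "write_frequency_table",
    "write_assignments",
]
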