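"""Observed-like synthetic datasets for end-to-end testing without any
download.

Two generators are provided:

* :func:`make_pseudo_observed` renders one coalescent draw from a known
  demography as an HVR-I sequence panel plus a Y-STR panel, in exactly the
  formats the real inputs use — the pseudo-observed datasets (PODs) of the
  model-recovery experiments.
* :func:`make_marker_fixture` builds binary Y-marker panels whose
  haplogroup composition follows the study template (per-population
  percentages at one decimal); percentages are converted to integer counts
  by largest-remainder rounding so each population hits its printed N
  exactly, and each sample carries derived calls along its haplogroup's
  root path and ancestral calls elsewhere.

The shipped default template transcribes the study's published sample
sizes and haplogroup compositions (24 populations, 519 Y-SNP males, three
language groups), so every pipeline stage can be exercised at the true
study scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .coalsim import (
    DemographyParams,
    MutationConfig,
    simulate_genealogy,
    drop_sequence_mutations,
    drop_str_mutations,
)
from .formats_io import (
    ANCESTRAL,
    DERIVED,
    CrossRefError,
    HaplogroupTree,
    MarkerPanel,
    read_haplogroup_tree,
)


@dataclass
class PopulationSpec:
    code: str
    name: str
    group: str  # KM | MK | TK
    n_hvri: int
    n_ystr: int
    n_ysnp: int
    haplogroup_percent: dict[str, float]

    def __post_init__(self) -> None:
        for n in (self.n_hvri, self.n_ystr, self.n_ysnp):
            if n <= 0:
                raise ValueError(f"{self.code}: sample sizes must be positive")
        total = sum(self.haplogroup_percent.values())
        if abs(total - 100.0) > 0.5:
            raise ValueError(
                f"{self.code}: haplogroup percentages sum to {total}, "
                "expected 100 +- 0.5"
            )


@dataclass
class StudyTemplate:
    """Population codes, group labels, sample sizes and haplogroup
    compositions defining the emulated study design."""

    populations: list[PopulationSpec]

    @classmethod
    def from_yaml(cls, path) -> "StudyTemplate":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc) -> "StudyTemplate":
        return cls([PopulationSpec(**p) for p in doc["populations"]])

    @classmethod
    def default(cls) -> "StudyTemplate":
        ref = resources.files("abcorigin") / "data" / "study_template.yaml"
        doc = yaml.safe_load(ref.read_text())
        return cls._from_doc(doc)

    def codes(self) -> list[str]:
        return [p.code for p in self.populations]

    def group_sample_sizes(self, marker_type: str) -> dict[str, int]:
        """Pooled per-group sizes (MK/KM/TK) for one marker system."""
        attr = {"HVRI": "n_hvri", "YSTR": "n_ystr", "YSNP": "n_ysnp"}[marker_type]
        out: dict[str, int] = {}
        for p in self.populations:
            out[p.group] = out.get(p.group, 0) + getattr(p, attr)
        return out

    def population(self, code: str) -> PopulationSpec:
        for p in self.populations:
            if p.code == code:
                return p
        raise KeyError(code)


def default_tree() -> HaplogroupTree:
    """The packaged 23-haplogroup marker tree (synthetic reconstruction)."""
    ref = resources.files("abcorigin") / "data" / "haplogroup_tree_synthetic.txt"
    with resources.as_file(ref) as path:
        return read_haplogroup_tree(path)


def largest_remainder_counts(percents: dict[str, float], n: int
                             ) -> dict[str, int]:
    """Convert one-decimal percentages to integer counts summing to ``n``.

    Floors ``pct * n / 100`` then distributes the shortfall to the largest
    fractional remainders (ties by insertion order, deterministic).
    """
    keys = list(percents)
    exact = np.array([percents[k] * n / 100.0 for k in keys])
    floors = np.floor(exact).astype(int)
    shortfall = n - int(floors.sum())
    if shortfall < 0:
        raise ValueError("percentages exceed 100 for this n")
    remainders = exact - floors
    order = np.argsort(-remainders, kind="stable")
    counts = floors.copy()
    for i in order[:shortfall]:
        counts[i] += 1
    return dict(zip(keys, counts.tolist()))


def make_marker_fixture(template: StudyTemplate, tree: HaplogroupTree,
                        seed: int | np.random.Generator = 0,
                        populations: list[str] | None = None) -> MarkerPanel:
    """Binary-marker panel realizing the template's haplogroup composition.

    Every sample of a population is given derived calls at all markers on
    its haplogroup's root path and ancestral calls at every other tree
    marker, so hierarchical re-assignment recovers the composition exactly.
    The seed only shuffles sample order within populations.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    marker_names = [m for name in tree.names_in_preorder()
                    for m in tree.nodes[name].markers]
    marker_idx = {m: j for j, m in enumerate(marker_names)}

    wanted = populations if populations is not None else template.codes()
    sample_ids: list[str] = []
    pop_labels: list[str] = []
    rows: list[np.ndarray] = []
    for code in wanted:
        spec = template.population(code)
        for hg in spec.haplogroup_percent:
            if hg not in tree.nodes:
                raise CrossRefError(
                    f"{code}: haplogroup {hg!r} is not a tree node"
                )
        counts = largest_remainder_counts(spec.haplogroup_percent, spec.n_ysnp)
        haplogroups = [hg for hg, c in counts.items() for _ in range(c)]
        rng.shuffle(haplogroups)
        for i, hg in enumerate(haplogroups):
            calls = np.full(len(marker_names), ANCESTRAL, dtype=np.int8)
            for node in tree.path_to_root(hg):
                for m in tree.nodes[node].markers:
                    calls[marker_idx[m]] = DERIVED
            sample_ids.append(f"{code}_{i + 1:03d}")
            pop_labels.append(code)
            rows.append(calls)
    return MarkerPanel(sample_ids, pop_labels, marker_names,
                       np.array(rows, dtype=np.int8))


def make_pseudo_observed(model_id: str, params: DemographyParams,
                         sample_sizes: dict[str, dict[str, int]] | dict[str, int],
                         mutation_config: MutationConfig, seed: int):
    """One POD: an HVR-I panel and a Y-STR panel from the same demography.

    The two marker systems are independent loci, so each gets its own
    genealogy draw.  ``sample_sizes`` either maps marker type to per-deme
    sizes (``{"HVRI": {...}, "YSTR": {...}}``) or gives one per-deme map
    used for both.  Byte-identical outputs for identical seeds.
    """
    if params.model_id != model_id:
        raise ValueError("params.model_id disagrees with model_id")
    if "HVRI" in sample_sizes:
        sizes_hvri = sample_sizes["HVRI"]
        sizes_ystr = sample_sizes["YSTR"]
    else:
        sizes_hvri = sizes_ystr = sample_sizes
    rng = np.random.default_rng(seed)
    gen_seq = simulate_genealogy(params, sizes_hvri, rng)
    seq_panel = drop_sequence_mutations(
        gen_seq, mutation_config.locus_length, mutation_config.mu_per_site,
        rng, kappa=mutation_config.kappa)
    gen_str = simulate_genealogy(params, sizes_ystr, rng)
    str_panel = drop_str_mutations(
        gen_str, mutation_config.locus_rates(), rng,
        ancestral_repeat=mutation_config.ancestral_repeat)
    return seq_panel, str_panel
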