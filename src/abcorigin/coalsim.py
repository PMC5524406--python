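"""Single-genealogy coalescent simulator for the two competing demographies.

Both models relate three present-day groups — Mon-Khmer (MK), Khon Mueang
(KM) and Tai-Kadai (TK) — through haploid constant-size demes:

* **tree-like**: KM and TK coalesce into one ancestral deme at ``T1``
  generations ago; that deme joins MK at ``T2 > T1``, after which a single
  ancestral deme of size ``N_anc`` remains.
* **admixture**: KM is founded at ``Tadm < T1`` by drawing each KM lineage
  from TK with probability ``alpha`` and from MK otherwise; MK and TK merge
  into the ancestral deme of size ``N_anc`` at ``T1``.

Within each deme the standard continuous-time haploid coalescent applies
(pair coalescence rate ``1/N`` per generation), with exact exponential
waiting times truncated at demographic events.  There is no migration
outside the admixture pulse, no recombination and no size change — the
study system is two non-recombining uniparental loci in populations whose
sizes are taken as constant over the modelled timescale.

One genealogy per simulation carries either a finite-sites sequence locus
(mtDNA HVR-I, transition-biased) or 17 fully linked microsatellites under
the strict stepwise mutation model (Y chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .formats_io import SequencePanel, STRPanel, DEFAULT_STR_LOCI, ReferenceTable
from .sumstats import (
    mtdna_summary_vector,
    mtdna_vector_from_codes,
    ystr_summary_vector,
)

DEMES = ("MK", "KM", "TK")
MODEL_ADMIXTURE = "admixture"
MODEL_TREELIKE = "tree_like"
MODELS = (MODEL_ADMIXTURE, MODEL_TREELIKE)

#: Canonical parameter column order in reference tables; parameters a model
#: does not use are stored as NaN.
PARAM_NAMES = ("N_MK", "N_KM", "N_TK", "N_anc", "T1", "T2", "Tadm", "alpha")


class ConfigurationError(ValueError):
    """Priors or demography parameters are mutually incompatible."""


@dataclass
class DemographyParams:
    """Parameters of one demography draw (haploid gene-copy sizes, times in
    generations before present)."""

    model_id: str
    N_MK: float
    N_KM: float
    N_TK: float
    N_anc: float
    T1: float
    T2: float = float("nan")
    Tadm: float = float("nan")
    alpha: float = float("nan")

    def __post_init__(self) -> None:
        if self.model_id not in MODELS:
            raise ConfigurationError(f"unknown model {self.model_id!r}")
        for name in ("N_MK", "N_KM", "N_TK", "N_anc"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.model_id == MODEL_TREELIKE:
            if not (0 < self.T1 < self.T2):
                raise ConfigurationError("tree-like model needs 0 < T1 < T2")
        else:
            if not (0 < self.Tadm < self.T1):
                raise ConfigurationError("admixture model needs 0 < Tadm < T1")
            if not (0 < self.alpha < 1):
                raise ConfigurationError("alpha must lie in (0, 1)")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PARAM_NAMES], dtype=float)


@dataclass
class PriorSet:
    """Independent uniform priors, one (lower, upper) pair per parameter.

    Ordering constraints (``T1 < T2``, ``Tadm < T1``) are enforced by
    rejection redraw in :func:`draw_params`, so bounds may overlap.
    """

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo <= hi:
                raise ConfigurationError(f"prior {name}: lower > upper")

    @classmethod
    def default(cls) -> "PriorSet":
        """Defaults consistent with a Tai-Kadai arrival about 2,000 years
        (~80 generations at 25 y/generation) before present."""
        return cls({
            "N_MK": (100.0, 50_000.0),
            "N_KM": (100.0, 50_000.0),
            "N_TK": (100.0, 50_000.0),
            "N_anc": (100.0, 50_000.0),
            "T1": (40.0, 120.0),
            "T2": (100.0, 4_000.0),
            "Tadm": (10.0, 120.0),
            "alpha": (0.0, 1.0),
        })

    def draw_one(self, name: str, rng: np.random.Generator) -> float:
        lo, hi = self.bounds[name]
        return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


_MODEL_PARAMS = {
    MODEL_TREELIKE: ("N_MK", "N_KM", "N_TK", "N_anc", "T1", "T2"),
    MODEL_ADMIXTURE: ("N_MK", "N_KM", "N_TK", "N_anc", "T1", "Tadm", "alpha"),
}

_MAX_REDRAWS = 1000


def draw_params(priors: PriorSet, model_id: str,
                rng: np.random.Generator) -> DemographyParams:
    """Draw one valid parameter vector; ordering constraints by redraw."""
    if model_id not in MODELS:
        raise ConfigurationError(f"unknown model {model_id!r}")
    for _ in range(_MAX_REDRAWS):
        draws = {p: priors.draw_one(p, rng) for p in _MODEL_PARAMS[model_id]}
        try:
            return DemographyParams(model_id=model_id, **draws)
        except ConfigurationError:
            continue
    raise ConfigurationError(
        f"could not draw valid {model_id} parameters in {_MAX_REDRAWS} "
        "attempts; check that the prior bounds are compatible"
    )


# ---------------------------------------------------------------------------
# genealogy


@dataclass
class Genealogy:
    """Binary coalescent tree: leaves ``0..n-1`` at time 0, internal nodes
    time-stamped in generations; ``parent[root] == -1``."""

    parent: np.ndarray
    time: np.ndarray
    leaf_populations: list[str]
    n_leaves: int

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=float)
        n = self.n_leaves
        if np.any(self.time[:n] != 0.0):
            raise ValueError("leaves must sit at time 0")
        lengths = self.branch_lengths()
        nonroot = self.parent >= 0
        if np.any(lengths[nonroot] <= 0):
            raise ValueError("branch lengths must be positive")

    def branch_lengths(self) -> np.ndarray:
        """Per-node length of the branch to its parent (0 for the root)."""
        out = np.zeros(len(self.parent))
        nonroot = self.parent >= 0
        out[nonroot] = self.time[self.parent[nonroot]] - self.time[nonroot]
        return out

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent < 0)[0][0])

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def nodes_root_first(self) -> np.ndarray:
        """Node indices ordered so parents precede children."""
        return np.argsort(-self.time, kind="stable")


def simulate_genealogy(params: DemographyParams,
                       sample_sizes: dict[str, int],
                       rng: np.random.Generator) -> Genealogy:
    """Simulate one genealogy under the demography.

    ``sample_sizes`` maps deme name (MK/KM/TK) to its number of sampled
    gene copies.  In the tree-like model the merged KM+TK deme keeps size
    ``N_TK`` between T1 and T2.
    """
    n_by_deme = {d: int(sample_sizes.get(d, 0)) for d in DEMES}
    n_total = sum(n_by_deme.values())
    if n_total < 2:
        raise ValueError("need at least two sampled lineages in total")

    n_nodes = 2 * n_total - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    leaf_populations: list[str] = []
    active: dict[str, list[int]] = {d: [] for d in DEMES}
    idx = 0
    for d in DEMES:
        for _ in range(n_by_deme[d]):
            active[d].append(idx)
            leaf_populations.append(d)
            idx += 1
    next_node = n_total

    sizes = {"MK": params.N_MK, "KM": params.N_KM, "TK": params.N_TK}

    def _merge_km_into_tk() -> None:
        active["TK"] += active["KM"]
        active["KM"] = []
        # ancestral KM+TK deme keeps the TK size until T2

    def _merge_all_into_mk_at_T2() -> None:
        active["MK"] += active["TK"]
        active["TK"] = []
        sizes["MK"] = params.N_anc

    def _admixture_pulse() -> None:
        for lineage in active["KM"]:
            target = "TK" if rng.random() < params.alpha else "MK"
            active[target].append(lineage)
        active["KM"] = []

    def _merge_parental_at_T1() -> None:
        active["MK"] += active["TK"]
        active["TK"] = []
        sizes["MK"] = params.N_anc

    if params.model_id == MODEL_TREELIKE:
        events = [(params.T1, _merge_km_into_tk),
                  (params.T2, _merge_all_into_mk_at_T2)]
    else:
        events = [(params.Tadm, _admixture_pulse),
                  (params.T1, _merge_parental_at_T1)]

    t = 0.0
    n_active = n_total
    while n_active > 1:
        demes = []
        rates = []
        total_rate = 0.0
        for d in DEMES:
            k = len(active[d])
            if k >= 2:
                r = k * (k - 1) / (2.0 * sizes[d])
                demes.append(d)
                rates.append(r)
                total_rate += r
        wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
        if events and t + wait >= events[0][0]:
            t, action = events.pop(0)
            action()
            continue
        t += wait
        if len(demes) == 1:
            deme = demes[0]
        else:  # competing exponentials: pick the deme by inverse cdf
            u = rng.random() * total_rate
            acc = 0.0
            deme = demes[-1]
            for d, r in zip(demes, rates):
                acc += r
                if u < acc:
                    deme = d
                    break
        pool = active[deme]
        k = len(pool)
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = pool[i], pool[j]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        # swap-remove the two merged lineages, append their parent
        for x in sorted((i, j), reverse=True):
            pool[x] = pool[-1]
            pool.pop()
        pool.append(next_node)
        next_node += 1
        n_active -= 1

    return Genealogy(parent=parent, time=time,
                     leaf_populations=leaf_populations, n_leaves=n_total)


# ---------------------------------------------------------------------------
# mutation models


@dataclass
class MutationConfig:
    """Mutation parameters for both marker types.

    ``mu_per_site`` is the HVR-I substitution rate per site per generation
    (pedigree-scale control-region rate); ``kappa`` the transition:
    transversion weighting; ``str_rate`` the per-locus per-generation
    stepwise mutation rate applied to each of ``n_str_loci`` loci unless
    ``str_locus_rates`` overrides them individually.
    """

    locus_length: int = 360
    mu_per_site: float = 5.0e-6
    kappa: float = 10.0
    str_rate: float = 6.9e-4
    n_str_loci: int = 17
    str_locus_rates: tuple[float, ...] | None = None
    ancestral_repeat: int = 20

    def locus_rates(self) -> np.ndarray:
        if self.str_locus_rates is not None:
            return np.asarray(self.str_locus_rates, dtype=float)
        return np.full(self.n_str_loci, self.str_rate)


_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)  # A<->G, C<->T
#: For each base, the two transversion targets.
_TRANSVERSION = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)
_DECODE = np.array(list("ACGT"))


def _mutate_codes(cur: np.ndarray, p_transition: float,
                  rng: np.random.Generator) -> np.ndarray:
    """One mutation step for each entry of ``cur`` (base codes 0..3)."""
    is_transition = rng.random(cur.size) < p_transition
    tv = _TRANSVERSION[cur, rng.integers(0, 2, size=cur.size)]
    return np.where(is_transition, _TRANSITION[cur], tv).astype(np.uint8)


def sequence_leaf_codes(gen: Genealogy, locus_length: int,
                        mu_per_site: float, rng: np.random.Generator,
                        kappa: float = 10.0,
                        ancestral: np.ndarray | None = None) -> np.ndarray:
    """Leaf base codes (n_leaves x L, codes 0..3) after scattering
    finite-sites mutations on the genealogy.

    The total mutation count is Poisson(total branch length x mu x L);
    each mutation picks a branch proportionally to its length and a uniform
    site.  At a site currently carrying base X, a mutation is a transition
    with probability ``kappa / (kappa + 2)`` and otherwise one of the two
    transversions, equiprobably.  Repeated hits at one site on one branch
    apply sequentially.
    """
    L = int(locus_length)
    bl = gen.branch_lengths()
    total = bl.sum()
    if ancestral is None:
        ancestral = rng.integers(0, 4, size=L, dtype=np.int64)
    ancestral = np.asarray(ancestral, dtype=np.uint8)
    if ancestral.shape != (L,):
        raise ValueError("ancestral sequence length mismatch")

    n_mut = rng.poisson(total * mu_per_site * L) if mu_per_site > 0 else 0
    per_branch = rng.multinomial(n_mut, bl / total) if n_mut else \
        np.zeros(len(bl), dtype=np.int64)

    # pre-draw all per-mutation randomness; mutations are assigned to
    # branches in index order (i.i.d., so any fixed assignment is valid)
    sites = rng.integers(0, L, size=n_mut)
    is_transition = rng.random(n_mut) < kappa / (kappa + 2.0)
    tv_choice = rng.integers(0, 2, size=n_mut)
    offsets = np.concatenate([[0], np.cumsum(per_branch)])
    transition = _TRANSITION
    transversion = _TRANSVERSION

    n_nodes = len(gen.parent)
    seqs = np.empty((n_nodes, L), dtype=np.uint8)
    for node in gen.nodes_root_first():
        p = gen.parent[node]
        seqs[node] = ancestral if p < 0 else seqs[p]
        row = seqs[node]
        for k in range(offsets[node], offsets[node + 1]):
            site = sites[k]
            cur = row[site]  # sequential: multiple hits overwrite
            row[site] = transition[cur] if is_transition[k] \
                else transversion[cur, tv_choice[k]]
    return seqs[: gen.n_leaves]


def drop_sequence_mutations(gen: Genealogy, locus_length: int,
                            mu_per_site: float, rng: np.random.Generator,
                            kappa: float = 10.0,
                            ancestral: np.ndarray | None = None,
                            ) -> SequencePanel:
    """Finite-sites mutation on a genealogy, rendered as a sequence panel
    (see :func:`sequence_leaf_codes` for the mutation process)."""
    leaves = sequence_leaf_codes(gen, locus_length, mu_per_site, rng,
                                 kappa=kappa, ancestral=ancestral)
    sequences = ["".join(_DECODE[row]) for row in leaves]
    sample_ids = [f"s{i}" for i in range(gen.n_leaves)]
    return SequencePanel(sample_ids, list(gen.leaf_populations),
                         sequences, int(locus_length))


def drop_str_mutations(gen: Genealogy, locus_rates,
                       rng: np.random.Generator,
                       ancestral_repeat: int = 20) -> STRPanel:
    """Strict stepwise mutation on fully linked STR loci sharing one
    genealogy.  Each mutation moves the repeat count by +-1 with equal
    probability; leaf counts are floored at one repeat."""
    rates = np.asarray(locus_rates, dtype=float)
    bl = gen.branch_lengths()
    total = bl.sum()
    n_nodes = len(gen.parent)
    L = len(rates)

    steps = np.zeros((n_nodes, L), dtype=np.int64)
    p_branch = bl / total
    for locus, rate in enumerate(rates):
        n_mut = rng.poisson(rate * total) if rate > 0 else 0
        if n_mut == 0:
            continue
        per_branch = rng.multinomial(n_mut, p_branch)
        ups = rng.binomial(per_branch, 0.5)
        steps[:, locus] = 2 * ups - per_branch

    values = np.empty((n_nodes, L), dtype=np.int64)
    for node in gen.nodes_root_first():
        p = gen.parent[node]
        values[node] = ancestral_repeat + steps[node] if p < 0 \
            else values[p] + steps[node]

    repeats = np.maximum(values[: gen.n_leaves], 1)
    sample_ids = [f"s{i}" for i in range(gen.n_leaves)]
    locus_names = list(DEFAULT_STR_LOCI[:L]) if L <= len(DEFAULT_STR_LOCI) \
        else [f"STR{i+1}" for i in range(L)]
    return STRPanel(sample_ids, list(gen.leaf_populations),
                    locus_names, repeats)


# ---------------------------------------------------------------------------
# reference-table simulation


def simulate_dataset(params: DemographyParams, marker_type: str,
                     sample_sizes: dict[str, int], config: MutationConfig,
                     rng: np.random.Generator):
    """One coalescent draw rendered as a panel of the requested type."""
    gen = simulate_genealogy(params, sample_sizes, rng)
    if marker_type == "HVRI":
        return drop_sequence_mutations(
            gen, config.locus_length, config.mu_per_site, rng,
            kappa=config.kappa)
    if marker_type == "YSTR":
        return drop_str_mutations(
            gen, config.locus_rates(), rng,
            ancestral_repeat=config.ancestral_repeat)
    raise ValueError(f"unknown marker type {marker_type!r}")


def _summary(panel, marker_type: str, pops: list[str]):
    if marker_type == "HVRI":
        return mtdna_summary_vector(panel, population_order=pops)
    return ystr_summary_vector(panel, population_order=pops)


def simulate_reference_table(model_id: str, priors: PriorSet, n_sims: int,
                             marker_type: str, sample_sizes: dict[str, int],
                             config: MutationConfig,
                             rng: np.random.Generator,
                             progress: bool = False) -> ReferenceTable:
    """Simulate ``n_sims`` (parameters, summary statistics) rows under one
    model.  Rows whose statistics are undefined are flagged, not dropped."""
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    pops = [d for d in DEMES if sample_sizes.get(d, 0) > 0]
    stat_names: list[str] | None = None
    params_rows = np.empty((n_sims, len(PARAM_NAMES)))
    stats_rows: np.ndarray | None = None
    iterator = range(n_sims)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm  # type: ignore[import-not-found]
        iterator = tqdm(iterator, desc=f"{model_id}/{marker_type}")
    for i in iterator:
        params = draw_params(priors, model_id, rng)
        if marker_type == "HVRI":
            # skip the string-panel round trip on the hot path
            gen = simulate_genealogy(params, sample_sizes, rng)
            codes = sequence_leaf_codes(
                gen, config.locus_length, config.mu_per_site, rng,
                kappa=config.kappa)
            vec = mtdna_vector_from_codes(codes, gen.leaf_populations, pops)
        else:
            panel = simulate_dataset(params, marker_type, sample_sizes,
                                     config, rng)
            vec = _summary(panel, marker_type, pops)
        if stat_names is None:
            stat_names = vec.names
            stats_rows = np.empty((n_sims, len(stat_names)))
        elif vec.names != stat_names:
            raise RuntimeError("statistic name order changed between rows")
        params_rows[i] = params.as_vector()
        stats_rows[i] = vec.values
    assert stats_rows is not None and stat_names is not None
    return ReferenceTable(
        model_ids=np.array([model_id] * n_sims, dtype=object),
        param_names=list(PARAM_NAMES),
        params=params_rows,
        stat_names=stat_names,
        stats=stats_rows,
    )


def with_overrides(config: MutationConfig, **kwargs) -> MutationConfig:
    """Copy a mutation config with individual fields replaced."""
    return replace(config, **kwargs)
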