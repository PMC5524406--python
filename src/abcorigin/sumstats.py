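"""Summary statistics for mtDNA HVR-I panels and Y-STR panels.

These are the fixed statistic suites applied identically to observed and
simulated data, so that ABC distances compare like with like:

* **HVRI** — per population: number of haplotypes, private polymorphic
  sites, Tajima's D, mean pairwise differences within; per unordered
  population pair: mean pairwise differences between and Hudson-style Fst
  (``1 - Hw/Hb`` on haplotype distances).
* **YSTR** — per population: mean and sample standard deviation over loci
  of four per-locus quantities (number of alleles, gene diversity, modified
  Garza-Williamson index ``k/(R+1)``, allelic range).

Missing data policy: sequence sites carrying ``N``/``-`` are deleted
pairwise from distance computations and excluded from site-based counts;
STR loci use only non-missing alleles.  A statistic whose preconditions
fail (e.g. Tajima's D with no segregating sites) is reported as NaN and
flagged rather than dropped, keeping vector layout fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .formats_io import MISSING_REPEAT, SequencePanel, STRPanel

#: Encoded value for missing sequence symbols inside uint8 matrices.
_SEQ_MISS = 255
_ENCODE = {b: i for i, b in enumerate("ACGT")}


@dataclass
class SummaryVector:
    """Ordered named statistics for one panel."""

    names: list[str]
    values: np.ndarray
    marker_type: str  # "HVRI" | "YSTR"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate statistic names")

    @property
    def flags(self) -> np.ndarray:
        """True where the statistic was undefined on this panel."""
        return ~np.isfinite(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def encode_sequences(seqs: list[str]) -> np.ndarray:
    """Pack aligned sequences into a uint8 matrix (missing -> 255)."""
    n, L = len(seqs), len(seqs[0]) if seqs else 0
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    raw = raw.reshape(n, L)
    out = np.full((n, L), _SEQ_MISS, dtype=np.uint8)
    for base, code in _ENCODE.items():
        out[raw == ord(base)] = code
    return out


def _base_presence(enc: np.ndarray) -> np.ndarray:
    """4 x L boolean matrix: base code present in any row at each site."""
    return np.stack([(enc == code).any(axis=0) for code in range(4)])


# ---------------------------------------------------------------------------
# haplotype / allele class statistics


def haplotype_diversity(class_counts) -> float:
    """Unbiased haplotype (gene) diversity ``h = n/(n-1) (1 - sum p_i^2)``.

    ``class_counts`` is the multiset of haplotype class sizes.  Undefined
    (NaN) for n < 2.
    """
    counts = np.asarray(list(class_counts), dtype=float)
    n = counts.sum()
    if n < 2:
        return float("nan")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p * p)))


def count_haplotypes(seqs: list[str]) -> int:
    """Number of distinct sequence haplotypes.

    The two missing symbols (``N`` and ``-``) are equivalent: sequences
    differing only in which missing symbol they carry are one haplotype.
    """
    return _count_haplotypes_enc(encode_sequences(seqs))


# ---------------------------------------------------------------------------
# sequence distances


def _pairwise_diff_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamming distances between all rows of ``a`` and ``b`` with pairwise
    deletion of missing sites; NaN for pairs with no usable site."""
    usable = (a[:, None, :] != _SEQ_MISS) & (b[None, :, :] != _SEQ_MISS)
    diff = (a[:, None, :] != b[None, :, :]) & usable
    n_usable = usable.sum(axis=2)
    d = diff.sum(axis=2).astype(float)
    d[n_usable == 0] = np.nan
    return d


def mean_pairwise_diff_within(seqs: list[str]) -> float:
    """Average number of differences over unordered within-sample pairs."""
    if len(seqs) < 2:
        return float("nan")
    enc = encode_sequences(seqs)
    d = _pairwise_diff_matrix(enc, enc)
    iu = np.triu_indices(len(seqs), k=1)
    vals = d[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def mean_pairwise_diff_between(seqs_a: list[str], seqs_b: list[str]) -> float:
    """Average number of differences over all A x B pairs."""
    if not seqs_a or not seqs_b:
        return float("nan")
    d = _pairwise_diff_matrix(encode_sequences(seqs_a), encode_sequences(seqs_b))
    vals = d[~np.isnan(d)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def segregating_sites(seqs: list[str]) -> int:
    """Sites with >= 2 distinct non-missing alleles."""
    presence = _base_presence(encode_sequences(seqs))
    return int((presence.sum(axis=0) >= 2).sum())


def tajimas_d(seqs: list[str]) -> float:
    """Tajima's D from pairwise diversity and segregating sites.

    Uses the standard constants a1, a2, b1, b2, c1, c2, e1, e2 for sample
    size n; undefined (NaN) when S = 0 or n < 2.
    """
    n = len(seqs)
    if n < 2:
        return float("nan")
    return _tajimas_d_from(n, segregating_sites(seqs),
                           mean_pairwise_diff_within(seqs))


def private_polymorphic_sites(focal_seqs: list[str],
                              other_seqs: list[str]) -> int:
    """Sites segregating within the focal population where the focal
    population carries an allele seen in no other population."""
    focal = _base_presence(encode_sequences(focal_seqs))
    segregating = focal.sum(axis=0) >= 2
    if not other_seqs:
        return int(segregating.sum())
    other = _base_presence(encode_sequences(other_seqs))
    has_private = (focal & ~other).any(axis=0)
    return int((segregating & has_private).sum())


def _within_diversity_n2(enc: np.ndarray) -> float:
    """Within-population diversity over *ordered* pairs including
    self-comparisons (denominator n^2); the convention that makes Fst of
    two identical panels exactly zero.  Unusable (all-missing) pairs are
    excluded; self pairs always contribute distance 0."""
    n = enc.shape[0]
    if n < 2:
        return float("nan")
    d = _pairwise_diff_matrix(enc, enc)
    vals = d[np.triu_indices(n, k=1)]
    valid = ~np.isnan(vals)
    if not valid.any():
        return float("nan")
    return float(2.0 * vals[valid].sum() / (2.0 * valid.sum() + n))


def _fst_from(hw_a: float, hw_b: float, hb: float) -> float:
    if not (np.isfinite(hw_a) and np.isfinite(hw_b) and np.isfinite(hb)):
        return float("nan")
    if hb == 0.0:
        return 0.0
    return float(min(1.0, max(-1.0, 1.0 - 0.5 * (hw_a + hw_b) / hb)))


def pairwise_fst_seq(seqs_a: list[str], seqs_b: list[str]) -> float:
    """Hudson-style Fst on haplotype distances: ``1 - Hw/Hb``.

    ``Hw`` is the mean of the two within-population diversities computed
    over ordered pairs including self-comparisons (so two identical panels
    give exactly 0); ``Hb`` is the mean distance over all A x B pairs.
    Degenerate ``Hb = 0`` returns 0; the result is clamped to [-1, 1].
    """
    hw_a = _within_diversity_n2(encode_sequences(seqs_a))
    hw_b = _within_diversity_n2(encode_sequences(seqs_b))
    hb = mean_pairwise_diff_between(seqs_a, seqs_b)
    return _fst_from(hw_a, hw_b, hb)


# ---------------------------------------------------------------------------
# STR locus statistics


def str_locus_stats(alleles: np.ndarray):
    """Per-locus (k, gene diversity, modified Garza-Williamson, range).

    ``alleles`` are the repeat counts of one locus in one population;
    missing entries (:data:`MISSING_REPEAT`) are removed first.  With fewer
    than two usable alleles the locus is unusable: all four values NaN.
    """
    obs = np.asarray(alleles)
    obs = obs[obs != MISSING_REPEAT]
    if obs.size < 2:
        nan = float("nan")
        return nan, nan, nan, nan
    values, counts = np.unique(obs, return_counts=True)
    k = float(len(values))
    diversity = haplotype_diversity(counts)
    rng = float(values.max() - values.min())
    gw = k / (rng + 1.0)
    return k, diversity, gw, rng


# ---------------------------------------------------------------------------
# full vectors


def _enc_pairwise_mean(a: np.ndarray, b: np.ndarray | None) -> float:
    """Mean pairwise difference from encoded matrices (within when ``b`` is
    None, between otherwise), with pairwise deletion of missing sites."""
    if b is None:
        if a.shape[0] < 2:
            return float("nan")
        d = _pairwise_diff_matrix(a, a)
        vals = d[np.triu_indices(a.shape[0], k=1)]
    else:
        if a.shape[0] == 0 or b.shape[0] == 0:
            return float("nan")
        vals = _pairwise_diff_matrix(a, b).ravel()
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def _tajimas_d_from(n: int, S: int, pi: float) -> float:
    if n < 2 or S == 0 or not np.isfinite(pi):
        return float("nan")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    num = pi - S / a1
    if var <= 0:
        # n = 2 analytic limit: the variance constants vanish but so does
        # the numerator (pi equals S when only one pair exists)
        return 0.0 if abs(num) < 1e-9 else float("nan")
    return float(num / np.sqrt(var))


def _count_haplotypes_enc(enc: np.ndarray) -> int:
    return len({row.tobytes() for row in enc})


def mtdna_vector_from_codes(enc: np.ndarray, pop_labels,
                            pops: list[str]) -> SummaryVector:
    """The HVRI suite computed from an already-encoded sequence matrix.

    This is the simulation hot path; :func:`mtdna_summary_vector` is the
    string-panel wrapper around it.
    """
    labels = np.asarray(pop_labels)
    idx_by_pop = {p: np.nonzero(labels == p)[0] for p in pops}
    enc_by_pop = {p: enc[idx_by_pop[p]] for p in pops}
    presence = {p: _base_presence(enc_by_pop[p]) for p in pops}
    if not (enc == _SEQ_MISS).any():
        # complete matrix: all pairwise distances in one BLAS product of
        # the one-hot encoding (distance = L - #matching sites)
        n, L = enc.shape
        onehot = np.zeros((n, 4 * L), dtype=np.float32)
        cols = np.arange(L) * 4 + enc
        onehot[np.arange(n)[:, None], cols] = 1.0
        # distances are exact small integers in float32; promote to float64
        # so the means agree with a direct computation to machine precision
        dist = (L - onehot @ onehot.T).astype(np.float64)
        pi_within = {}
        hw_n2 = {}
        for p in pops:
            idx = idx_by_pop[p]
            if len(idx) < 2:
                pi_within[p] = hw_n2[p] = float("nan")
                continue
            block = dist[np.ix_(idx, idx)]
            off_sum = block[np.triu_indices(len(idx), k=1)].sum()
            pi_within[p] = float(
                off_sum / (len(idx) * (len(idx) - 1) / 2))
            hw_n2[p] = float(2.0 * off_sum / len(idx) ** 2)
        pi_between = {
            (p, q): float(
                dist[np.ix_(idx_by_pop[p], idx_by_pop[q])].mean())
            if len(idx_by_pop[p]) and len(idx_by_pop[q]) else float("nan")
            for p, q in combinations(pops, 2)
        }
    else:
        pi_within = {p: _enc_pairwise_mean(enc_by_pop[p], None) for p in pops}
        hw_n2 = {p: _within_diversity_n2(enc_by_pop[p]) for p in pops}
        pi_between = {
            (p, q): _enc_pairwise_mean(enc_by_pop[p], enc_by_pop[q])
            for p, q in combinations(pops, 2)
        }
    names: list[str] = []
    values: list[float] = []
    for p in pops:
        sub = enc_by_pop[p]
        segregating = presence[p].sum(axis=0) >= 2
        others = [q for q in pops if q != p]
        if others:
            other_presence = np.logical_or.reduce(
                [presence[q] for q in others])
            private = (presence[p] & ~other_presence).any(axis=0)
            n_private = int((segregating & private).sum())
        else:
            n_private = int(segregating.sum())
        names += [f"nhap_{p}", f"private_sites_{p}", f"tajimas_d_{p}",
                  f"pi_within_{p}"]
        values += [
            float(_count_haplotypes_enc(sub)),
            float(n_private),
            _tajimas_d_from(sub.shape[0], int(segregating.sum()),
                            pi_within[p]),
            pi_within[p],
        ]
    for p, q in combinations(pops, 2):
        names.append(f"pi_between_{p}_{q}")
        values.append(pi_between[(p, q)])
    for p, q in combinations(pops, 2):
        names.append(f"fst_{p}_{q}")
        values.append(_fst_from(hw_n2[p], hw_n2[q], pi_between[(p, q)]))
    return SummaryVector(names, np.array(values), "HVRI")


def mtdna_summary_vector(panel: SequencePanel,
                         population_order: list[str] | None = None,
                         ) -> SummaryVector:
    """The HVRI statistic suite with a deterministic name order.

    For K populations: 4K within-population statistics, then
    K(K-1)/2 between-population mean differences, then K(K-1)/2 Fst values,
    pairs enumerated in population order.
    """
    pops = population_order if population_order is not None \
        else panel.population_order()
    enc = encode_sequences(panel.sequences)
    return mtdna_vector_from_codes(enc, panel.populations, pops)


_YSTR_PARAMS = ("nalleles", "diversity", "gw", "range")


def ystr_summary_vector(panel: STRPanel,
                        population_order: list[str] | None = None,
                        ) -> SummaryVector:
    """The YSTR statistic suite: per population, mean and sd (ddof=1) over
    loci of the four per-locus statistics -> 8 named values per population.

    Loci with fewer than two non-missing alleles in a population are
    excluded from that population's means; a population with fewer than two
    usable loci gets NaN (flagged) entries.
    """
    groups = panel.by_population()
    pops = population_order if population_order is not None else list(groups)
    names: list[str] = []
    values: list[float] = []
    for p in pops:
        mat = groups[p]
        per_locus = np.array(
            [str_locus_stats(mat[:, j]) for j in range(mat.shape[1])]
        )  # L x 4, NaN rows for unusable loci
        usable = ~np.isnan(per_locus).any(axis=1)
        stats_ok = per_locus[usable]
        for s, stat_name in enumerate(_YSTR_PARAMS):
            names += [f"{stat_name}_mean_{p}", f"{stat_name}_sd_{p}"]
            if stats_ok.shape[0] >= 2:
                col = stats_ok[:, s]
                values += [float(col.mean()), float(col.std(ddof=1))]
            else:
                values += [float("nan"), float("nan")]
    return SummaryVector(names, np.array(values), "YSTR")


def summary_vector_names(marker_type: str, pops: list[str]) -> list[str]:
    """Statistic names for a marker type and population order, without data."""
    if marker_type == "HVRI":
        names = []
        for p in pops:
            names += [f"nhap_{p}", f"private_sites_{p}", f"tajimas_d_{p}",
                      f"pi_within_{p}"]
        names += [f"pi_between_{p}_{q}" for p, q in combinations(pops, 2)]
        names += [f"fst_{p}_{q}" for p, q in combinations(pops, 2)]
        return names
    if marker_type == "YSTR":
        return [f"{s}_{kind}_{p}" for p in pops for s in _YSTR_PARAMS
                for kind in ("mean", "sd")]
    raise ValueError(f"unknown marker type {marker_type!r}")


def write_summary_vector(vec: SummaryVector, path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tvalue\tflag\n")
        for name, value, flag in zip(vec.names, vec.values, vec.flags):
            fh.write(f"{name}\t{float(value)!r}\t{int(flag)}\n")
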