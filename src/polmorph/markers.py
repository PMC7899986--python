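"""Diversity and differentiation for dominant binary markers and sequences.

Dominant markers (e.g. ISSR band-presence data) show only band present /
absent, so allele frequencies are estimated under Hardy-Weinberg as
q = sqrt(1 - band frequency) for the recessive null allele. Per-locus
diversity statistics follow the usual biallelic definitions:

    H_e = 2pq,  uH_e = H_e * 2N/(2N-1),  N_e = 1/(p^2 + q^2),
    I = -(p ln p + q ln q)

Population differentiation uses a two-level AMOVA on squared-Euclidean
band-vector distances (the binary analogue of F_ST, phi_PT), with a
label-permutation test. Sequence divergence uses Jukes-Cantor distances
with pairwise deletion of gaps/ambiguities, partitioned into within- and
among-group diversity with a Nei-style coefficient of differentiation
(d_T - d_S)/d_T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "MarkerMatrix",
    "Alignment",
    "AmovaResult",
    "DiversityPartition",
    "read_marker_matrix",
    "write_marker_matrix",
    "dominant_allele_freqs",
    "diversity_stats",
    "amova_phipt",
    "read_alignment",
    "write_alignment",
    "jc_distance",
    "group_diversities",
]

_VALID_BASES = frozenset(b"ACGT")


@dataclass
class MarkerMatrix:
    """Binary band-presence matrix (individuals x loci) with population labels."""

    data: np.ndarray
    individuals: list[str]
    populations: list[str]
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("marker data must be 2-D")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("marker entries must be 0 or 1")
        n, m = self.data.shape
        if n < 2:
            raise ValueError("need at least 2 individuals")
        if len(self.individuals) != n or len(self.populations) != n:
            raise ValueError("individual/population labels do not match rows")
        if not self.loci:
            self.loci = [f"L{j + 1:03d}" for j in range(m)]
        if len(self.loci) != m:
            raise ValueError("locus labels do not match columns")

    @property
    def band_freq(self) -> np.ndarray:
        return self.data.mean(axis=0)

    @property
    def monomorphic(self) -> np.ndarray:
        """Loci with no variation across all individuals."""
        f = self.band_freq
        return (f == 0.0) | (f == 1.0)


def read_marker_matrix(path) -> MarkerMatrix:
    """Read a band matrix: columns ``individual,population,<locus>...``, 0/1 cells."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if list(df.columns[:2]) != ["individual", "population"]:
        raise ValueError("first two columns must be 'individual,population'")
    loci = list(df.columns[2:])
    return MarkerMatrix(
        df[loci].to_numpy(),
        [str(v) for v in df["individual"]],
        [str(v) for v in df["population"]],
        loci,
    )


def write_marker_matrix(path, matrix: MarkerMatrix) -> None:
    df = pd.DataFrame(matrix.data, columns=matrix.loci)
    df.insert(0, "population", matrix.populations)
    df.insert(0, "individual", matrix.individuals)
    df.to_csv(path, index=False)


def dominant_allele_freqs(matrix: MarkerMatrix) -> pd.DataFrame:
    """Per-locus allele frequencies for dominant markers under HWE.

    q (null allele) = sqrt(1 - band frequency); p = 1 - q. Monomorphic loci
    are flagged.
    """
    f = matrix.band_freq
    q = np.sqrt(1.0 - f)
    return pd.DataFrame(
        {
            "band_freq": f,
            "p": 1.0 - q,
            "q": q,
            "monomorphic": matrix.monomorphic,
        },
        index=matrix.loci,
    )


def diversity_stats(matrix: MarkerMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus N_e, I, H_e, uH_e plus their mean and SE over loci."""
    freqs = dominant_allele_freqs(matrix)
    p, q = freqs["p"].to_numpy(), freqs["q"].to_numpy()
    n = len(matrix.individuals)
    h_e = 2.0 * p * q
    n_e = 1.0 / (p**2 + q**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        i_idx = -(np.where(p > 0, p * np.log(p), 0.0) + np.where(q > 0, q * np.log(q), 0.0))
    uh_e = h_e * (2.0 * n) / (2.0 * n - 1.0)
    per_locus = pd.DataFrame(
        {"N_e": n_e, "I": i_idx, "H_e": h_e, "uH_e": uh_e}, index=matrix.loci
    )
    m = per_locus.shape[0]
    summary = pd.DataFrame(
        {"mean": per_locus.mean(), "se": per_locus.std(ddof=1) / np.sqrt(m)}
    )
    return per_locus, summary


@dataclass
class AmovaResult:
    phi_pt: float
    p_value: float | None
    var_among: float
    var_within: float
    pct_among: float
    pct_within: float
    df_among: int
    df_within: int
    n_permutations: int


def _within_ss(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for pop in np.unique(labels):
        idx = np.flatnonzero(labels == pop)
        sub = d2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * idx.size)
    return ss


def amova_phipt(
    matrix: MarkerMatrix, n_permutations: int = 999, seed: int | None = None
) -> AmovaResult:
    """Two-level AMOVA on binary band vectors: phi_PT and permutation p.

    Distances are squared Euclidean (the band-difference count for 0/1
    data). Variance components use the standard moment estimators with the
    average-sample-size correction n0 = (N - sum n_i^2 / N)/(k - 1);
    phi_PT = var_among / (var_among + var_within). The p-value is
    (# permuted phi >= observed + 1)/(n_permutations + 1), permuting
    population labels under ``seed``; pass ``n_permutations=0`` to skip it.
    """
    labels = np.asarray(matrix.populations)
    pops, counts = np.unique(labels, return_counts=True)
    if pops.size < 2:
        raise ValueError("need at least 2 populations")
    if counts.min() < 2:
        raise ValueError("every population needs at least 2 individuals")
    x = matrix.data.astype(float)
    n_tot = x.shape[0]
    k = pops.size
    g = np.inner(x, x)
    sq = np.diag(g)
    d2 = sq[:, None] + sq[None, :] - 2.0 * g  # squared Euclidean

    ss_total = d2.sum() / (2.0 * n_tot)
    ss_within = _within_ss(d2, labels)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n_tot - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n_tot - (counts**2).sum() / n_tot) / (k - 1)
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    total = var_among + var_within

    def phi(va, vw):
        return 0.0 if va + vw == 0 else va / (va + vw)

    phi_obs = phi(var_among, var_within)
    p_value = None
    if n_permutations:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            ssw = _within_ss(d2, perm)
            msa = (ss_total - ssw) / df_among
            msw = ssw / df_within
            va = (msa - msw) / n0
            if phi(va, msw) >= phi_obs:
                hits += 1
        p_value = (hits + 1) / (n_permutations + 1)
    return AmovaResult(
        phi_pt=float(phi_obs),
        p_value=p_value,
        var_among=float(var_among),
        var_within=float(var_within),
        pct_among=float(100.0 * var_among / total) if total else 0.0,
        pct_within=float(100.0 * var_within / total) if total else 100.0,
        df_among=df_among,
        df_within=df_within,
        n_permutations=n_permutations,
    )


@dataclass
class Alignment:
    """Equal-length sequences over {A,C,G,T,-,N} with a group label each."""

    ids: list[str]
    groups: list[str]
    seqs: np.ndarray  # (n, L) array of single-byte characters

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype="S1")
        if self.seqs.ndim != 2 or self.seqs.shape[0] < 2:
            raise ValueError("alignment needs >= 2 equal-length sequences")
        if len(self.ids) != self.seqs.shape[0] or len(self.groups) != self.seqs.shape[0]:
            raise ValueError("ids/groups do not match sequence count")
        allowed = frozenset(b"ACGT-N")
        present = {bytes(b) for b in np.unique(self.seqs)}
        bad = {c for c in present if c[0] not in allowed}
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return self.seqs.shape[1]


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA; headers ``>id|group`` carry the group label."""
    ids, groups, rows = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, group = rec.id.partition("|")
        ids.append(name)
        groups.append(group or "ungrouped")
        rows.append(np.frombuffer(str(rec.seq).upper().encode(), dtype="S1"))
    if len({r.size for r in rows}) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return Alignment(ids, groups, np.vstack(rows))


def write_alignment(path, alignment: Alignment) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, (name, group) in enumerate(zip(alignment.ids, alignment.groups)):
            fh.write(f">{name}|{group}\n")
            fh.write(alignment.seqs[i].tobytes().decode() + "\n")


def jc_distance(alignment: Alignment, pairwise_deletion: bool = True) -> pd.DataFrame:
    """Pairwise Jukes-Cantor distances d = -(3/4) ln(1 - (4/3) p-hat.

    Gap and N sites are dropped per pair (pairwise deletion) or globally
    (complete deletion). Saturated pairs (p-hat >= 0.75) and pairs with no
    comparable sites are reported as NaN.
    """
    seqs = alignment.seqs
    valid = np.isin(seqs, [b"A", b"C", b"G", b"T"])
    if not pairwise_deletion:
        keep = valid.all(axis=0)
        seqs = seqs[:, keep]
        valid = valid[:, keep]
    n = seqs.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            n_sites = int(both.sum())
            if n_sites == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            p_hat = float((seqs[i, both] != seqs[j, both]).mean())
            if p_hat >= 0.75:
                d[i, j] = d[j, i] = np.nan  # beyond Jukes-Cantor saturation
            else:
                d[i, j] = d[j, i] = -0.75 * np.log1p(-4.0 * p_hat / 3.0)
    return pd.DataFrame(d, index=alignment.ids, columns=alignment.ids)


@dataclass
class DiversityPartition:
    within_group: pd.Series  # mean pairwise d per group
    among_group: pd.DataFrame  # mean pairwise d per group pair
    d_s: float  # average within-group diversity
    d_t: float  # total mean diversity
    coefficient: float  # (d_T - d_S)/d_T; NaN when d_T == 0
    coefficient_se: float | None = None


def _partition(dist: np.ndarray, groups: np.ndarray):
    iu = np.triu_indices_from(dist, k=1)
    d_t = np.nanmean(dist[iu])
    names = np.unique(groups)
    within = {}
    for gname in names:
        idx = np.flatnonzero(groups == gname)
        if idx.size < 2:
            within[gname] = np.nan
            continue
        sub = dist[np.ix_(idx, idx)]
        within[gname] = np.nanmean(sub[np.triu_indices(idx.size, k=1)])
    d_s = np.nanmean(list(within.values()))
    coeff = np.nan if d_t == 0 or np.isnan(d_t) else (d_t - d_s) / d_t
    return within, d_s, d_t, coeff, names


def group_diversities(
    distance_matrix: pd.DataFrame,
    groups,
    alignment: Alignment | None = None,
    n_bootstrap: int = 500,
    seed: int | None = None,
) -> DiversityPartition:
    """Partition mean pairwise distances within/among groups.

    ``groups`` maps sequence id -> group (or is a sequence aligned to the
    matrix index). The coefficient of differentiation is (d_T - d_S)/d_T.
    When the source ``alignment`` is supplied, its sites are bootstrapped
    (``n_bootstrap`` replicates, seeded) to attach an SE to the coefficient.
    """
    ids = list(distance_matrix.index)
    if isinstance(groups, dict):
        missing = [i for i in ids if i not in groups]
        if missing:
            raise ValueError(f"sequences without a group: {missing}")
        garr = np.asarray([groups[i] for i in ids])
    else:
        garr = np.asarray(list(groups))
        if garr.size != len(ids):
            raise ValueError("group labels do not match matrix size")
    dist = distance_matrix.to_numpy(dtype=float)
    within, d_s, d_t, coeff, names = _partition(dist, garr)

    among = pd.DataFrame(np.nan, index=names, columns=names)
    for a_i, a in enumerate(names):
        for b in names[a_i + 1 :]:
            ia = np.flatnonzero(garr == a)
            ib = np.flatnonzero(garr == b)
            among.loc[a, b] = among.loc[b, a] = np.nanmean(dist[np.ix_(ia, ib)])

    se = None
    if alignment is not None and not np.isnan(coeff):
        rng = np.random.default_rng(seed)
        length = alignment.length
        reps = []
        for _ in range(n_bootstrap):
            sites = rng.integers(0, length, size=length)
            boot = Alignment(alignment.ids, alignment.groups, alignment.seqs[:, sites])
            bd = jc_distance(boot).to_numpy(dtype=float)
            reps.append(_partition(bd, garr)[3])
        se = float(np.nanstd(reps, ddof=1))
    return DiversityPartition(
        within_group=pd.Series(within),
        among_group=among,
        d_s=float(d_s),
        d_t=float(d_t),
        coefficient=float(coeff) if not np.isnan(coeff) else np.nan,
        coefficient_se=se,
    )
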