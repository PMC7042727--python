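"""Exact single-locus parametric linkage analysis on loop-free pedigrees.

The likelihood of affection statuses and marker genotypes is computed jointly
over a two-locus haplotype (disease allele, marker allele) per transmitted
gamete, by message passing over the nuclear-family tree (Elston-Stewart
peeling).  Computations are vectorized over a recombination-fraction grid and
over batches of simulated marker replicates, which makes the paramlink-style
maximal-LOD power simulation cheap.

``enumeration_likelihood`` is a deliberately naive full-joint enumeration used
as an independent oracle in the test-suite; it shares no code with the peeler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .pedigree import AFFECTED, UNAFFECTED, Pedigree

__all__ = [
    "DiseaseModel",
    "MarkerLocus",
    "LinkageResult",
    "pedigree_likelihood",
    "enumeration_likelihood",
    "lod_score",
    "max_lod_power",
    "max_lod_distribution",
    "sample_disease_genotypes",
    "region_intersect",
    "default_theta_grid",
]


@dataclass(frozen=True)
class DiseaseModel:
    """Single-locus disease model: allele frequency and penetrance triple."""

    disease_allele_freq: float
    penetrances: tuple[float, float, float]

    def __post_init__(self) -> None:
        q = self.disease_allele_freq
        if not 0.0 < q < 1.0:
            raise ValueError(f"disease allele frequency must be in (0,1), got {q}")
        if len(self.penetrances) != 3:
            raise ValueError("penetrances must be a (f0, f1, f2) triple")
        for f in self.penetrances:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"penetrance {f} outside [0,1]")


#: The study's rare fully-penetrant dominant model.
DOMINANT_MODEL = DiseaseModel(0.0001, (0.0001, 1.0, 1.0))


@dataclass
class MarkerLocus:
    """A co-dominant marker with known allele frequencies.

    ``genotypes`` maps individual id to an unordered allele-index pair, or
    ``None`` for an untyped individual.
    """

    alleles: tuple[str, ...]
    freqs: np.ndarray
    genotypes: dict[str, Optional[tuple[int, int]]] = field(default_factory=dict)
    name: str = "marker"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.alleles) != self.freqs.shape[0]:
            raise ValueError("allele labels and frequencies differ in length")
        if np.any(self.freqs <= 0):
            raise ValueError("marker allele frequencies must be positive")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("marker allele frequencies must sum to 1")


@dataclass
class LinkageResult:
    theta_grid: np.ndarray
    lod: np.ndarray
    max_lod: float
    theta_max: float


def default_theta_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 0.5 + 1e-12, 0.01), 10)


# ---------------------------------------------------------------------------
# Peeling engine
# ---------------------------------------------------------------------------


class PedigreePeeler:
    """Batched exact likelihood of (affections, marker genotypes | ped, model, theta).

    State encoding: a haplotype is ``h = d * A + m`` with ``d`` the disease
    allele (0/1) and ``m`` the marker allele (0..A-1); an individual's ordered
    genotype is ``s = h_pat * H + h_mat`` with ``H = 2A`` haplotypes, giving
    ``S = H * H`` states.
    """

    def __init__(self, ped: Pedigree, model: DiseaseModel, marker_freqs: Sequence[float]):
        self.ped = ped
        self.model = model
        self.marker_freqs = np.asarray(marker_freqs, dtype=float)
        if np.any(self.marker_freqs <= 0) or abs(self.marker_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("marker allele frequencies must be positive and sum to 1")
        self.A = len(self.marker_freqs)
        self.H = 2 * self.A
        self.S = self.H * self.H
        self.ids = ped.ids
        self.index = {iid: k for k, iid in enumerate(self.ids)}

        h = np.arange(self.H)
        self._hap_d = h // self.A
        self._hap_m = h % self.A
        s = np.arange(self.S)
        self._s_hp = s // self.H
        self._s_hm = s % self.H

        q = model.disease_allele_freq
        hap_prior = np.where(self._hap_d == 1, q, 1.0 - q) * self.marker_freqs[self._hap_m]
        self._state_prior = hap_prior[self._s_hp] * hap_prior[self._s_hm]

        f = np.asarray(model.penetrances)
        ndis = self._hap_d[self._s_hp] + self._hap_d[self._s_hm]
        self._pen = {
            AFFECTED: f[ndis],
            UNAFFECTED: 1.0 - f[ndis],
            "unknown": np.ones(self.S),
        }

        self._families = ped.nuclear_families()
        self._fam_of_child: dict[str, int] = {}
        self._fams_of_parent: dict[str, list[int]] = {}
        for k, (fa, mo, children) in enumerate(self._families):
            for c in children:
                self._fam_of_child[c] = k
            self._fams_of_parent.setdefault(fa, []).append(k)
            self._fams_of_parent.setdefault(mo, []).append(k)
        self._check_no_loops()

    # -- structure ---------------------------------------------------------

    def _fams_of(self, iid: str) -> list[int]:
        fams = list(self._fams_of_parent.get(iid, []))
        if iid in self._fam_of_child:
            fams.append(self._fam_of_child[iid])
        return fams

    def _check_no_loops(self) -> None:
        # the individual/family incidence graph must be a forest
        n_edges = sum(
            2 + len(ch) for (_, _, ch) in self._families
        )
        nodes: set[str] = set()
        for fa, mo, ch in self._families:
            nodes.update([fa, mo, *ch])
        n_nodes = len(nodes) + len(self._families)
        n_components = self._count_components()
        isolated = len(self.ids) - len(nodes)
        if n_edges != n_nodes - (n_components - isolated):
            raise ValueError("pedigree contains a loop; peeling supports trees only")

    def _count_components(self) -> int:
        parent: dict[str, str] = {iid: iid for iid in self.ids}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: str, b: str) -> None:
            parent[find(a)] = find(b)

        for fa, mo, ch in self._families:
            union(fa, mo)
            for c in ch:
                union(fa, c)
        return len({find(i) for i in self.ids})

    # -- transmissions -----------------------------------------------------

    def _gamete_tensor(self, thetas: np.ndarray) -> np.ndarray:
        """P(transmitted haplotype | ordered parent genotype) per theta: (T,S,H)."""
        T = thetas.shape[0]
        out = np.zeros((T, self.S, self.H))
        hp, hm = self._s_hp, self._s_hm
        d_p, m_p = self._hap_d[hp], self._hap_m[hp]
        d_m, m_m = self._hap_d[hm], self._hap_m[hm]
        for t, th in enumerate(thetas):
            probs = [
                ((1 - th) / 2, d_p, m_p),
                ((1 - th) / 2, d_m, m_m),
                (th / 2, d_p, m_m),
                (th / 2, d_m, m_p),
            ]
            for w, d, m in probs:
                np.add.at(out[t], (np.arange(self.S), d * self.A + m), w)
        return out

    # -- observations ------------------------------------------------------

    def _obs_vector(self, geno: np.ndarray) -> np.ndarray:
        """Indicator (R, S) from unordered marker genotypes (R, 2), -1 = missing."""
        R = geno.shape[0]
        mp = self._hap_m[self._s_hp]
        mm = self._hap_m[self._s_hm]
        g1 = geno[:, 0][:, None]
        g2 = geno[:, 1][:, None]
        missing = (geno[:, 0] < 0) | (geno[:, 1] < 0)
        match = ((mp[None, :] == g1) & (mm[None, :] == g2)) | (
            (mp[None, :] == g2) & (mm[None, :] == g1)
        )
        out = np.where(missing[:, None], 1.0, match.astype(float))
        return out

    # -- likelihood --------------------------------------------------------

    def loglikelihood(
        self,
        marker_genotypes: np.ndarray,
        thetas: Sequence[float],
    ) -> np.ndarray:
        """log10 L for a batch of marker data sets over a theta grid: (R, T).

        ``marker_genotypes`` is (R, n_individuals, 2) of allele indices with
        -1 for missing; individual axis follows ``ped.individuals`` order.
        Entries for individuals not flagged ``genotyped`` are ignored.
        """
        thetas = np.asarray(thetas, dtype=float)
        if np.any(thetas < 0) or np.any(thetas > 0.5):
            raise ValueError("theta must lie in [0, 0.5]")
        geno = np.asarray(marker_genotypes)
        if geno.ndim == 2:
            geno = geno[None, :, :]
        R = geno.shape[0]
        Tn = thetas.shape[0]

        self._Tg = self._gamete_tensor(thetas)
        self._logscale = np.zeros((R, Tn))

        unary: list[np.ndarray] = []
        for k, ind in enumerate(self.ped.individuals):
            u = self._pen[ind.affection][None, None, :] * np.ones((R, 1, 1))
            if ind.genotyped:
                u = u * self._obs_vector(geno[:, k, :])[:, None, :]
            if ind.is_founder:
                u = u * self._state_prior[None, None, :]
            unary.append(np.broadcast_to(u, (R, Tn, self.S)).copy())
        self._unary = unary

        total = np.zeros((R, Tn))
        seen: set[str] = set()
        for iid in self.ids:
            if iid in seen:
                continue
            comp = self._component_of(iid)
            seen.update(comp)
            up = self._up(iid, None)
            L = up.sum(axis=2)
            with np.errstate(divide="ignore"):
                total += np.where(L > 0, np.log10(np.maximum(L, 1e-300)), -np.inf)
        total += self._logscale
        del self._unary, self._Tg, self._logscale
        return total

    def _component_of(self, iid: str) -> set[str]:
        comp = {iid}
        frontier = [iid]
        while frontier:
            cur = frontier.pop()
            for k in self._fams_of(cur):
                fa, mo, ch = self._families[k]
                for other in (fa, mo, *ch):
                    if other not in comp:
                        comp.add(other)
                        frontier.append(other)
        return comp

    def _rescale(self, arr: np.ndarray) -> np.ndarray:
        scale = arr.max(axis=-1)
        safe = np.where(scale > 0, scale, 1.0)
        with np.errstate(divide="ignore"):
            self._logscale += np.where(scale > 0, np.log10(safe), -np.inf)
        return arr / safe[..., None]

    def _up(self, iid: str, exclude_fam: Optional[int]) -> np.ndarray:
        """unary(iid) times messages from all adjacent families but one: (R,T,S)."""
        out = self._unary[self.index[iid]].copy()
        for k in self._fams_of(iid):
            if k == exclude_fam:
                continue
            out = out * self._msg(k, iid)
        return self._rescale(out)

    def _child_factor(self, child: str, fam: int) -> np.ndarray:
        """sum_{s_c} P(s_c | s_f, s_m) up(c): (R, T, S_f, S_m)."""
        u = self._up(child, fam)
        R, Tn, _ = u.shape
        u4 = u.reshape(R, Tn, self.H, self.H)
        # paternal gamete from father's state, maternal from mother's
        return np.einsum("tfp,tgq,rtpq->rtfg", self._Tg, self._Tg, u4, optimize=True)

    def _msg(self, fam: int, pivot: str) -> np.ndarray:
        fa, mo, children = self._families[fam]
        if pivot in (fa, mo):
            spouse = mo if pivot == fa else fa
            w = np.ones((1, 1, self.S, self.S))
            for c in children:
                w = w * self._child_factor(c, fam)
            u_sp = self._up(spouse, fam)
            if pivot == fa:
                msg = np.einsum("rtfg,rtg->rtf", w, u_sp, optimize=True)
            else:
                msg = np.einsum("rtfg,rtf->rtg", w, u_sp, optimize=True)
            return msg
        # pivot is a child of this family
        w = np.ones((1, 1, self.S, self.S))
        for c in children:
            if c != pivot:
                w = w * self._child_factor(c, fam)
        u_f = self._up(fa, fam)
        u_m = self._up(mo, fam)
        v = w * u_f[:, :, :, None] * u_m[:, :, None, :]
        msg = np.einsum("rtfg,tfp,tgq->rtpq", v, self._Tg, self._Tg, optimize=True)
        R, Tn = msg.shape[:2]
        return msg.reshape(R, Tn, self.S)


def _marker_array(ped: Pedigree, marker: MarkerLocus) -> np.ndarray:
    geno = np.full((1, len(ped), 2), -1, dtype=int)
    for k, ind in enumerate(ped.individuals):
        g = marker.genotypes.get(ind.id)
        if g is not None:
            geno[0, k, 0], geno[0, k, 1] = g
    return geno


def _typed_pedigree(ped: Pedigree, marker: MarkerLocus) -> Pedigree:
    typed = {iid for iid, g in marker.genotypes.items() if g is not None}
    return ped.with_genotyped(typed)


def pedigree_likelihood(
    ped: Pedigree, model: DiseaseModel, marker: MarkerLocus, theta: float
) -> float:
    """Exact P(affections, marker genotypes | pedigree, model, theta)."""
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta must lie in [0, 0.5], got {theta}")
    p = PedigreePeeler(_typed_pedigree(ped, marker), model, marker.freqs)
    ll = p.loglikelihood(_marker_array(ped, marker), [theta])
    return float(10.0 ** ll[0, 0]) if np.isfinite(ll[0, 0]) else 0.0


def lod_score(
    ped: Pedigree,
    model: DiseaseModel,
    marker: MarkerLocus,
    theta_grid: Optional[Sequence[float]] = None,
) -> LinkageResult:
    """LOD(theta) = log10 L(theta) - log10 L(0.5) over a grid of thetas."""
    grid = default_theta_grid() if theta_grid is None else np.asarray(theta_grid, float)
    thetas = np.append(grid, 0.5)
    p = PedigreePeeler(_typed_pedigree(ped, marker), model, marker.freqs)
    ll = p.loglikelihood(_marker_array(ped, marker), thetas)[0]
    if not np.isfinite(ll[-1]):
        raise ValueError("likelihood at theta=0.5 is zero: data impossible")
    lod = ll[:-1] - ll[-1]
    imax = int(np.nanargmax(np.where(np.isfinite(lod), lod, -np.inf)))
    return LinkageResult(
        theta_grid=grid,
        lod=lod,
        max_lod=float(lod[imax]),
        theta_max=float(grid[imax]),
    )


# ---------------------------------------------------------------------------
# Independent enumeration oracle
# ---------------------------------------------------------------------------


def enumeration_likelihood(
    ped: Pedigree,
    model: DiseaseModel,
    marker: MarkerLocus,
    theta: float,
    max_cells: int = 40_000_000,
) -> float:
    """Brute-force likelihood by summing the full joint over ordered genotypes.

    Intended as a test oracle only: the joint probability table over every
    individual's ordered (disease, marker) genotype is materialized, so the
    product of per-individual consistent-state counts must stay below
    ``max_cells``.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    A = len(marker.freqs)
    H = 2 * A
    S = H * H
    q = model.disease_allele_freq
    f = model.penetrances
    freqs = np.asarray(marker.freqs, float)

    def hap(h: int) -> tuple[int, int]:
        return h // A, h % A

    hap_prior = np.array([(q if hap(h)[0] else 1 - q) * freqs[hap(h)[1]] for h in range(H)])

    # per-state descriptors
    state_d = np.zeros(S, int)
    state_m = np.zeros((S, 2), int)
    for s in range(S):
        hp, hm = s // H, s % H
        state_d[s] = hap(hp)[0] + hap(hm)[0]
        state_m[s] = (hap(hp)[1], hap(hm)[1])

    # gamete distribution per ordered parent state, then ordered-child table
    gam = np.zeros((S, H))
    for s in range(S):
        hp, hm = s // H, s % H
        (dp, mp), (dm, mm) = hap(hp), hap(hm)
        gam[s, dp * A + mp] += (1 - theta) / 2
        gam[s, dm * A + mm] += (1 - theta) / 2
        gam[s, dp * A + mm] += theta / 2
        gam[s, dm * A + mp] += theta / 2
    trans = np.zeros((S, S, S))  # child, father, mother
    for c in range(S):
        trans[c] = np.outer(gam[:, c // H], gam[:, c % H])

    order = ped.topological_order()
    pos = {ind.id: k for k, ind in enumerate(order)}

    allowed: list[np.ndarray] = []
    unaries: list[np.ndarray] = []
    for ind in order:
        u = np.ones(S)
        for s in range(S):
            k = state_d[s]
            if ind.affection == AFFECTED:
                u[s] *= f[k]
            elif ind.affection == UNAFFECTED:
                u[s] *= 1 - f[k]
        g = marker.genotypes.get(ind.id)
        if g is not None:
            for s in range(S):
                ms = (state_m[s, 0], state_m[s, 1])
                if ms != tuple(g) and ms != tuple(g)[::-1]:
                    u[s] = 0.0
        if ind.is_founder:
            for s in range(S):
                u[s] *= hap_prior[s // H] * hap_prior[s % H]
        keep = np.nonzero(u > 0)[0]
        if keep.size == 0:
            return 0.0
        allowed.append(keep)
        unaries.append(u[keep])

    n = len(order)
    total_cells = int(np.prod([len(a) for a in allowed], dtype=float))
    if total_cells > max_cells:
        raise ValueError(f"enumeration too large: {total_cells} cells")

    def axis_shape(k: int, size: int) -> tuple[int, ...]:
        return tuple(size if j == k else 1 for j in range(n))

    joint = np.ones([len(a) for a in allowed])
    for k, ind in enumerate(order):
        joint *= unaries[k].reshape(axis_shape(k, len(allowed[k])))
        if not ind.is_founder:
            kf, km = pos[ind.father_id], pos[ind.mother_id]
            sub = trans[np.ix_(allowed[k], allowed[kf], allowed[km])]
            joint *= _place3(sub, k, kf, km, n)
    return float(joint.sum())


def _place3(sub: np.ndarray, k: int, kf: int, km: int, n: int) -> np.ndarray:
    """Reshape a (child, father, mother) table to broadcast over an n-axis joint."""
    axes = [k, kf, km]
    order = np.argsort(axes)
    sub = np.transpose(sub, order)
    shape = [1] * n
    for a, size in zip(sorted(axes), sub.shape):
        shape[a] = size
    return sub.reshape(shape)


# ---------------------------------------------------------------------------
# Conditional disease-genotype sampling and power simulation
# ---------------------------------------------------------------------------


class _DiseaseSampler:
    """Exact sampling of ordered disease genotypes given affections (tree FFBS).

    States: s = d_pat * 2 + d_mat in {0,1,2,3}.
    """

    def __init__(self, ped: Pedigree, model: DiseaseModel):
        self.ped = ped
        q = model.disease_allele_freq
        f = np.asarray(model.penetrances)
        s = np.arange(4)
        dp, dm = s // 2, s % 2
        self.prior = np.where(dp, q, 1 - q) * np.where(dm, q, 1 - q)
        ndis = dp + dm
        self.pen = {
            AFFECTED: f[ndis],
            UNAFFECTED: 1 - f[ndis],
            "unknown": np.ones(4),
        }
        # trans[s_c, s_f, s_m]
        gam = np.zeros((4, 2))
        for st in range(4):
            gam[st, st // 2] += 0.5
            gam[st, st % 2] += 0.5
        t = np.zeros((4, 4, 4))
        for sc in range(4):
            t[sc] = np.outer(gam[:, sc // 2], gam[:, sc % 2])
        self.trans = t

        self.families = ped.nuclear_families()
        self.fam_of_child: dict[str, int] = {}
        self.fams_of_parent: dict[str, list[int]] = {}
        for k, (fa, mo, ch) in enumerate(self.families):
            for c in ch:
                self.fam_of_child[c] = k
            self.fams_of_parent.setdefault(fa, []).append(k)
            self.fams_of_parent.setdefault(mo, []).append(k)
        self.unary = {}
        for ind in ped.individuals:
            u = self.pen[ind.affection].copy()
            if ind.is_founder:
                u = u * self.prior
            self.unary[ind.id] = u

    def _fams_of(self, iid: str) -> list[int]:
        out = list(self.fams_of_parent.get(iid, []))
        if iid in self.fam_of_child:
            out.append(self.fam_of_child[iid])
        return out

    def up(self, iid: str, exclude: Optional[int]) -> np.ndarray:
        out = self.unary[iid].copy()
        for k in self._fams_of(iid):
            if k != exclude:
                out = out * self.msg(k, iid)
        tot = out.sum()
        if tot <= 0:
            raise ValueError("affection data impossible under disease model")
        return out / tot

    def child_factor(self, child: str, fam: int) -> np.ndarray:
        u = self.up(child, fam)
        return np.einsum("cfm,c->fm", self.trans, u)

    def msg(self, fam: int, pivot: str) -> np.ndarray:
        fa, mo, children = self.families[fam]
        if pivot in (fa, mo):
            spouse = mo if pivot == fa else fa
            w = np.ones((4, 4))
            for c in children:
                w = w * self.child_factor(c, fam)
            u_sp = self.up(spouse, fam)
            return w @ u_sp if pivot == fa else u_sp @ w
        w = np.ones((4, 4))
        for c in children:
            if c != pivot:
                w = w * self.child_factor(c, fam)
        v = w * np.outer(self.up(fa, fam), self.up(mo, fam))
        return np.einsum("cfm,fm->c", self.trans, v)

    @staticmethod
    def _draw(rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Vectorized categorical draw; rows (R, K) of unnormalized weights."""
        cdf = np.cumsum(rows, axis=1)
        u = rng.random(rows.shape[0]) * cdf[:, -1]
        return np.argmax(cdf >= u[:, None], axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, n_individuals) array of ordered disease-genotype states."""
        ids = self.ped.ids
        idx = {iid: k for k, iid in enumerate(ids)}
        out = np.full((n, len(ids)), -1, dtype=np.int8)

        done_fams: set[int] = set()
        assigned: set[str] = set()

        def assign_root(iid: str) -> None:
            w = self.up(iid, None)
            out[:, idx[iid]] = self._draw(np.broadcast_to(w, (n, 4)), rng)
            assigned.add(iid)
            expand(iid)

        def expand(iid: str) -> None:
            for k in self._fams_of(iid):
                if k in done_fams:
                    continue
                done_fams.add(k)
                fa, mo, children = self.families[k]
                if iid in (fa, mo):
                    spouse = mo if iid == fa else fa
                    if spouse not in assigned:
                        w = np.ones((4, 4))
                        for c in children:
                            w = w * self.child_factor(c, k)
                        u_sp = self.up(spouse, k)
                        piv = out[:, idx[iid]]
                        rows = (w if iid == fa else w.T)[piv] * u_sp[None, :]
                        out[:, idx[spouse]] = self._draw(rows, rng)
                        assigned.add(spouse)
                    for c in children:
                        sf = out[:, idx[fa]]
                        sm = out[:, idx[mo]]
                        rows = self.trans[:, sf, sm].T * self.up(c, k)[None, :]
                        out[:, idx[c]] = self._draw(rows, rng)
                        assigned.add(c)
                    for other in (spouse, *children):
                        expand(other)
                else:
                    # iid is a child: sample parents jointly, then siblings
                    w = np.ones((4, 4))
                    for c in children:
                        if c != iid:
                            w = w * self.child_factor(c, k)
                    v = w * np.outer(self.up(fa, k), self.up(mo, k))
                    sc = out[:, idx[iid]]
                    rows = (self.trans[sc] * v[None, :, :]).reshape(n, 16)
                    joint = self._draw(rows, rng)
                    out[:, idx[fa]] = joint // 4
                    out[:, idx[mo]] = joint % 4
                    assigned.update([fa, mo])
                    for c in children:
                        if c == iid:
                            continue
                        sf = out[:, idx[fa]]
                        sm = out[:, idx[mo]]
                        rows = self.trans[:, sf, sm].T * self.up(c, k)[None, :]
                        out[:, idx[c]] = self._draw(rows, rng)
                        assigned.add(c)
                    for other in (fa, mo, *[c for c in children if c != iid]):
                        expand(other)

        for iid in ids:
            if iid not in assigned:
                assign_root(iid)
        return out


def sample_disease_genotypes(
    ped: Pedigree, model: DiseaseModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ordered disease genotypes (d_pat*2 + d_mat) given affections."""
    return _DiseaseSampler(ped, model).sample(n, rng)


def _drop_linked_marker(
    ped: Pedigree,
    disease_states: np.ndarray,
    rng: np.random.Generator,
    n_alleles: int = 4,
) -> np.ndarray:
    """Gene-drop an equifrequent marker fully linked (theta=0) to the disease locus.

    Returns ordered marker haplotype alleles (R, n, 2) [paternal, maternal].
    """
    R, n = disease_states.shape
    idx = {iid: k for k, iid in enumerate(ped.ids)}
    haps = np.full((R, n, 2), -1, dtype=np.int8)
    for ind in ped.topological_order():
        k = idx[ind.id]
        if ind.is_founder:
            haps[:, k, 0] = rng.integers(0, n_alleles, R)
            haps[:, k, 1] = rng.integers(0, n_alleles, R)
        else:
            for slot, pid in ((0, ind.father_id), (1, ind.mother_id)):
                kp = idx[pid]
                sp = disease_states[:, kp]
                dp, dm = sp // 2, sp % 2
                want = (disease_states[:, k] // 2) if slot == 0 else (disease_states[:, k] % 2)
                # choose the parental haplotype carrying the transmitted
                # disease allele; uniform when the parent is homozygous
                hom = dp == dm
                choice = np.where(dp == want, 0, 1)
                choice = np.where(hom, rng.integers(0, 2, R), choice)
                haps[:, k, slot] = haps[np.arange(R), kp, choice]
    return haps


def max_lod_distribution(
    ped: Pedigree,
    model: DiseaseModel,
    typed_ids: Iterable[str],
    n_markers: int,
    seed: int,
    theta_grid: Optional[Sequence[float]] = None,
    n_alleles: int = 4,
    chunk: int = 1000,
) -> np.ndarray:
    """Per-replicate maximal LOD for fully linked simulated markers: (n_markers,).

    Markers are gene-dropped at theta=0 with ``n_alleles`` equifrequent
    alleles, so each replicate co-segregates perfectly and its LOD is
    maximal at theta=0; the default theta grid is therefore just [0].
    """
    typed = set(typed_ids)
    if not typed:
        raise ValueError("typed_ids must not be empty")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    ped_t = ped.with_genotyped(typed)
    grid = (
        np.array([0.0]) if theta_grid is None else np.asarray(theta_grid, float)
    )
    thetas = np.append(grid, 0.5)
    rng = np.random.default_rng(seed)
    sampler = _DiseaseSampler(ped_t, model)
    peeler = PedigreePeeler(ped_t, model, np.full(n_alleles, 1.0 / n_alleles))
    typed_mask = np.array([ind.id in typed for ind in ped_t.individuals])

    out = np.empty(n_markers)
    pos = 0
    while pos < n_markers:
        R = min(chunk, n_markers - pos)
        dstates = sampler.sample(R, rng)
        haps = _drop_linked_marker(ped_t, dstates, rng)
        geno = haps.astype(int)
        geno[:, ~typed_mask, :] = -1
        ll = peeler.loglikelihood(geno, thetas)
        lod = ll[:, :-1] - ll[:, -1][:, None]
        lod = np.where(np.isfinite(lod), lod, -np.inf)
        out[pos : pos + R] = lod.max(axis=1)
        pos += R
    return out


def max_lod_power(
    ped: Pedigree,
    model: DiseaseModel,
    typed_ids: Iterable[str],
    n_markers: int = 10_000,
    seed: int = 0,
    **kwargs,
) -> float:
    """Maximal observed LOD over ``n_markers`` simulated fully linked markers."""
    lods = max_lod_distribution(ped, model, typed_ids, n_markers, seed, **kwargs)
    return float(lods.max())


# ---------------------------------------------------------------------------
# Region intersection
# ---------------------------------------------------------------------------


def region_intersect(variants, regions) -> list:
    """Variants whose position falls inside any region (1-based inclusive)."""
    by_chrom: dict[str, list] = {}
    for r in regions:
        by_chrom.setdefault(str(r.chrom), []).append((r.start, r.end))
    out = []
    for v in variants:
        for start, end in by_chrom.get(str(v.chrom), []):
            if start <= v.pos <= end:
                out.append(v)
                break
    return out
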