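"""Windowed admixture-graph inference between populations.

Populations are summarised by log-balances of allele frequencies (one row per
population, one column per SNP). A migration hypothesis is a rooted base tree
whose branch lengths are free drift variances, plus an ordered list of
admixture events: population ``y`` is formed as a weighted mixture of Q
source lineages ``z_q`` (weights ``w`` on the simplex), then accumulates its
own variance ``t_y``. Each ``z_q`` is the precursor of a current population
``x_q`` and shares a fraction ``alpha_q`` of that population's own (post-
split) variance. Events may nest: a mixture target can be a source later.

The hypothesis induces a covariance matrix V over populations, hence a
matrix ``D_jk = V_jj + V_kk - 2 V_jk`` of variances of balance differences.
Within a genomic window w the root-mean-square distance ``d_w(j, k)`` between
two populations' balance rows is modelled as ``N(0, D_jk)``; the objective
summed over unordered pairs, plus a Dirichlet(lambda) regularizer on the
mixture weights, is maximized separately per window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io_geno import SnpMeta

__all__ = [
    "BalanceMatrix",
    "Window",
    "AdmixtureEvent",
    "AdmixtureGraph",
    "WindowFit",
    "FitConfig",
    "build_windows",
    "rms_distance",
    "graph_covariance",
    "objective",
    "fit_windows",
    "variance_decomposition",
    "compare_hypotheses",
    "parse_hypothesis",
]


@dataclass
class BalanceMatrix:
    """Population x SNP log-balances with genomic metadata."""

    pop_ids: list[str]
    snp_ids: list[str]
    X: np.ndarray  # (P, N)
    meta: SnpMeta | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.pop_ids), len(self.snp_ids)):
            raise ValueError("X shape does not match id lists")
        if len(self.pop_ids) < 2:
            raise ValueError("need at least two populations")
        if not np.isfinite(self.X).all():
            raise ValueError("balances must be finite")

    @classmethod
    def from_frequencies(cls, freqs: pd.DataFrame, meta: SnpMeta | None = None) -> "BalanceMatrix":
        """Build from a population x SNP frequency table (values in (0, 1))."""
        from .popdisp_model import balance

        return cls(list(freqs.index), list(freqs.columns), balance(freqs.to_numpy()), meta)


@dataclass
class Window:
    """Half-open genomic interval [start, end) with the indices of the SNPs
    (columns of the balance matrix) that fall inside it."""

    chrom: str
    start: int
    end: int
    snp_index: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.snp_index)


def build_windows(
    meta: SnpMeta, window_size: int = 3_000_000, step: int = 1_000_000, min_snps: int = 10
) -> list[Window]:
    """Sliding windows per chromosome.

    Starts at 0 and advances by ``step`` while the window fits inside the
    chromosome span (max position + 1); if the span is shorter than one
    window, a single window covers it. Windows holding fewer than
    ``min_snps`` SNPs are dropped.
    """
    if not (window_size >= step > 0):
        raise ValueError("need window_size >= step > 0")
    if len(meta) == 0:
        return []
    out: list[Window] = []
    pos = meta.pos
    chroms = meta.chrom
    for chrom in dict.fromkeys(chroms.tolist()):
        on = np.flatnonzero(chroms == chrom)
        span = int(pos[on].max()) + 1
        starts = list(range(0, max(span - window_size, 0) + 1, step))
        if not starts:
            starts = [0]
        for s0 in starts:
            inside = on[(pos[on] >= s0) & (pos[on] < s0 + window_size)]
            if len(inside) >= min_snps:
                out.append(Window(str(chrom), s0, s0 + window_size, inside))
    return out


def rms_distance(X, j: int, k: int, window: Window) -> float:
    """Root-mean-square distance between populations j and k over the SNPs of
    a window: ``sqrt(mean_i (x_ji - x_ki)^2)``."""
    arr = X.X if isinstance(X, BalanceMatrix) else np.asarray(X, dtype=float)
    if window.n_snps == 0:
        raise ValueError("empty window")
    d = arr[j, window.snp_index] - arr[k, window.snp_index]
    return float(np.sqrt(np.mean(d * d)))


@dataclass
class AdmixtureEvent:
    """One admixture event: ``target`` is a mixture of ``sources``.

    Fitted parameters (weights, own variance ``t_y``, per-source sharing
    ``alpha``) live in the parameter vector, not here; ``tie_alpha`` collapses
    the per-source sharing fractions to a single scalar for the event.
    """

    target: str
    sources: list[str]
    tie_alpha: bool = False

    def __post_init__(self) -> None:
        if len(self.sources) < 2:
            raise ValueError("an admixture event needs at least two sources")
        if self.target in self.sources:
            raise ValueError(f"event target {self.target} cannot be its own source")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_alpha(self) -> int:
        return 1 if self.tie_alpha else len(self.sources)


class AdmixtureGraph:
    """Base population tree plus ordered admixture events.

    The base tree comes from a Newick string whose branch lengths are free
    parameters (numeric values in the string are used as initial values /
    truth in simulation). The parameter vector is laid out as::

        [branch lengths (one per tree edge)] +
        per event: [w_1..w_Q, t_y, alpha (1 or Q)]
    """

    def __init__(self, newick: str, events: list[AdmixtureEvent] | None = None):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        self.leaf_names: list[str] = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("duplicate leaf names in base tree")
        # edges with a parent (root edge carries no drift)
        self._edges = []  # list of (set of leaf names below, initial length)
        self._terminal_edge: dict[str, int] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            below = {lf.taxon.label for lf in node.leaf_iter()}
            init = node.edge.length if node.edge.length is not None else 0.1
            if len(below) == 1:
                self._terminal_edge[next(iter(below))] = len(self._edges)
            self._edges.append((below, float(init)))
        self.events = list(events or [])
        self.pop_ids: list[str] = list(self.leaf_names)
        defined = set(self.pop_ids)
        for ev in self.events:
            for s in ev.sources:
                if s not in defined:
                    raise ValueError(
                        f"event source {s!r} is not defined before its event (cycle or typo)"
                    )
            if ev.target in defined:
                raise ValueError(f"event target {ev.target!r} already defined (cycle)")
            defined.add(ev.target)
            self.pop_ids.append(ev.target)

    # -- parameter vector layout -------------------------------------------
    @property
    def n_branches(self) -> int:
        return len(self._edges)

    @property
    def n_params(self) -> int:
        return self.n_branches + sum(ev.n_sources + 1 + ev.n_alpha for ev in self.events)

    def param_names(self) -> list[str]:
        names = [f"branch_{i}" for i in range(self.n_branches)]
        for ev in self.events:
            names += [f"{ev.target}.w[{s}]" for s in ev.sources]
            names.append(f"{ev.target}.t_own")
            if ev.tie_alpha:
                names.append(f"{ev.target}.alpha")
            else:
                names += [f"{ev.target}.alpha[{s}]" for s in ev.sources]
        return names

    def default_params(self) -> np.ndarray:
        p = [init for _, init in self._edges]
        for ev in self.events:
            p += [1.0 / ev.n_sources] * ev.n_sources
            p.append(0.1)
            p += [0.5] * ev.n_alpha
        return np.array(p, dtype=float)

    def unpack(self, params: np.ndarray):
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters")
        branches = params[: self.n_branches]
        pos = self.n_branches
        evp = []
        for ev in self.events:
            q = ev.n_sources
            w = params[pos : pos + q]
            pos += q
            t_y = params[pos]
            pos += 1
            alpha = params[pos : pos + ev.n_alpha]
            pos += ev.n_alpha
            if ev.tie_alpha:
                alpha = np.repeat(alpha, q)
            evp.append((w, float(t_y), alpha))
        return branches, evp

    # -- covariance construction -------------------------------------------
    def _components(self, params: np.ndarray):
        """Build variance components and population loadings.

        Returns (loadings dict pop -> {comp: coef}, comp variances list,
        own components dict pop -> list of comp indices,
        event rows: per event (target, sources, w, t_y, z loadings list)).
        """
        branches, evp = self.unpack(params)
        if (branches < 0).any():
            raise ValueError("branch lengths must be nonnegative")
        comp_var: list[float] = []
        load: dict[str, dict[int, float]] = {name: {} for name in self.leaf_names}
        own: dict[str, list[int]] = {}
        for (below, _), t in zip(self._edges, branches):
            c = len(comp_var)
            comp_var.append(float(t))
            for name in below:
                load[name][c] = 1.0
        for name, eidx in self._terminal_edge.items():
            own[name] = [eidx]

        event_records = []
        for ev, (w, t_y, alpha) in zip(self.events, evp):
            if (w < -1e-9).any() or abs(w.sum() - 1) > 1e-6:
                raise ValueError(f"weights of event {ev.target} must lie on the simplex")
            if t_y < 0 or (alpha < -1e-9).any() or (alpha > 1 + 1e-9).any():
                raise ValueError(f"t_y >= 0 and alpha in [0,1] required for {ev.target}")
            z_loads = []
            for src, al in zip(ev.sources, alpha):
                # split each own component of the source into a shared part
                # (fraction alpha, carried by z) and a private part
                z = dict(load[src])
                new_own = []
                for c in own[src]:
                    v = comp_var[c]
                    comp_var[c] = al * v
                    c2 = len(comp_var)
                    comp_var.append((1 - al) * v)
                    for pop in load:
                        if c in load[pop]:
                            load[pop][c2] = load[pop][c]
                    z.pop(c2, None)
                    new_own.extend([c, c2])
                own[src] = new_own
                z_loads.append(z)
            y_load: dict[int, float] = {}
            for wq, z in zip(w, z_loads):
                for c, coef in z.items():
                    y_load[c] = y_load.get(c, 0.0) + wq * coef
            c_own = len(comp_var)
            comp_var.append(t_y)
            y_load[c_own] = 1.0
            load[ev.target] = y_load
            own[ev.target] = [c_own]
            event_records.append((ev, w, t_y, z_loads, c_own))
        return load, np.array(comp_var), own, event_records

    def covariance(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Covariance V over populations (order ``pop_ids``) and the derived
        difference-variance matrix ``D_jk = V_jj + V_kk - 2 V_jk``."""
        load, comp_var, _, _ = self._components(params)
        P = len(self.pop_ids)
        ncomp = len(comp_var)
        L = np.zeros((P, ncomp))
        for pi, pop in enumerate(self.pop_ids):
            for c, coef in load[pop].items():
                L[pi, c] = coef
        V = (L * comp_var) @ L.T
        V = 0.5 * (V + V.T)
        d = np.diag(V)
        D = d[:, None] + d[None, :] - 2 * V
        np.fill_diagonal(D, 0.0)
        return V, D

    def decompose(self, params: np.ndarray) -> dict[str, dict[str, float]]:
        """Variance decomposition of every admixture target.

        Source q's share is ``w_q cov(z_q, y) / V_yy`` (which reduces to
        ``w_q^2 var(z_q) / V_yy`` for independent sources) and the own share
        is ``t_y / V_yy``; shares are nonnegative and sum to one exactly.
        """
        load, comp_var, _, event_records = self._components(params)

        def cov(d1: dict[int, float], d2: dict[int, float]) -> float:
            return sum(coef * d2.get(c, 0.0) * comp_var[c] for c, coef in d1.items())

        out: dict[str, dict[str, float]] = {}
        for ev, w, t_y, z_loads, _ in event_records:
            y_load = load[ev.target]
            v_yy = cov(y_load, y_load)
            if v_yy <= 0:
                raise ValueError(f"target {ev.target} has zero variance; decomposition undefined")
            shares = {}
            for src, wq, z in zip(ev.sources, w, z_loads):
                shares[src] = wq * cov(z, y_load) / v_yy
            shares["__own__"] = t_y / v_yy
            out[ev.target] = shares
        return out


def graph_covariance(graph: AdmixtureGraph, params: np.ndarray):
    """Functional alias for :meth:`AdmixtureGraph.covariance`."""
    return graph.covariance(params)


_HALF_LOG_2PI = 0.5 * np.log(2 * np.pi)


def objective(
    params: np.ndarray,
    X: BalanceMatrix,
    window: Window,
    graph: AdmixtureGraph,
    lam: float = 0.9,
) -> float:
    """Log objective for one window: Gaussian log-density of the pairwise RMS
    distances under ``D`` plus the Dirichlet(lambda) weight penalty
    ``(lambda - 1) sum_q log w_q`` per event; ``lam = 1`` disables it."""
    _, D = graph.covariance(params)
    total = 0.0
    P = len(X.pop_ids)
    gidx = {p: graph.pop_ids.index(p) for p in X.pop_ids}
    for j in range(P - 1):
        for k in range(j + 1, P):
            d = rms_distance(X, j, k, window)
            djk = D[gidx[X.pop_ids[j]], gidx[X.pop_ids[k]]]
            if djk <= 0:
                if d > 0:
                    return -np.inf
                continue
            total += -_HALF_LOG_2PI - 0.5 * np.log(djk) - d * d / (2 * djk)
    _, evp = graph.unpack(params)
    for (w, _, _), ev in zip(evp, graph.events):
        wq = np.clip(w, 1e-300, None)
        total += (lam - 1.0) * float(np.sum(np.log(wq)))
    return float(total)


@dataclass
class FitConfig:
    """Per-window optimizer settings (bounded quasi-Newton, multi-start)."""

    n_starts: int = 5
    seed: int = 0
    lam: float = 0.9
    maxiter: int = 500
    tol: float = 1e-8


@dataclass
class WindowFit:
    """Estimates for one window: natural-scale parameters, objective value and
    the variance decomposition of every admixed population."""

    window: Window
    params: np.ndarray
    param_names: list[str]
    objective: float
    decomposition: dict[str, dict[str, float]]
    converged: bool


class _Transform:
    """Unconstrained <-> natural parameters: log for variances, softmax for
    each event's weights (first logit pinned to 0), logistic for alphas."""

    def __init__(self, graph: AdmixtureGraph):
        self.graph = graph
        self.n_free = graph.n_branches + sum(
            (ev.n_sources - 1) + 1 + ev.n_alpha for ev in graph.events
        )

    def to_natural(self, z: np.ndarray) -> np.ndarray:
        g = self.graph
        out = np.empty(g.n_params)
        out[: g.n_branches] = np.exp(np.clip(z[: g.n_branches], -40, 40))
        zp = g.n_branches
        np_ = g.n_branches
        for ev in g.events:
            q = ev.n_sources
            raw = np.concatenate([[0.0], z[zp : zp + q - 1]])
            zp += q - 1
            raw = raw - raw.max()
            w = np.exp(raw)
            w /= w.sum()
            out[np_ : np_ + q] = w
            np_ += q
            out[np_] = np.exp(np.clip(z[zp], -40, 40))
            zp += 1
            np_ += 1
            for _ in range(ev.n_alpha):
                out[np_] = 1.0 / (1.0 + np.exp(-np.clip(z[zp], -40, 40)))
                zp += 1
                np_ += 1
        return out

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.normal(scale=1.0, size=self.n_free)
        z[: self.graph.n_branches] = rng.normal(loc=-1.0, scale=1.0, size=self.graph.n_branches)
        return z


def fit_windows(
    X: BalanceMatrix,
    windows: list[Window],
    graph: AdmixtureGraph,
    config: FitConfig | None = None,
) -> list[WindowFit]:
    """Maximize the objective separately in every window.

    Parameters are optimized on an unconstrained scale (log variances,
    softmax weights, logistic sharing fractions) with L-BFGS-B from
    ``n_starts`` seeded random starts; deterministic given ``config.seed``. A
    window whose optimizer fails is flagged (``converged=False``) and the
    remaining windows are unaffected.
    """
    config = config or FitConfig()
    missing = [p for p in graph.pop_ids if p not in X.pop_ids]
    if missing:
        raise ValueError(f"balance matrix lacks populations {missing}")
    tr = _Transform(graph)
    names = graph.param_names()
    w_slices = []
    pos = graph.n_branches
    for ev in graph.events:
        w_slices.append(slice(pos, pos + ev.n_sources))
        pos += ev.n_sources + 1 + ev.n_alpha
    fits: list[WindowFit] = []
    for wi, window in enumerate(windows):
        rng = np.random.default_rng(config.seed + 1000 * wi)

        def neg(z):
            p = tr.to_natural(z)
            val = objective(p, X, window, graph, lam=config.lam)
            # maximize in the unconstrained space: the Dirichlet prior on w
            # picks up the softmax log-Jacobian sum(log w); without it the
            # lambda < 1 density has no mode (it diverges at the boundary)
            for sl in w_slices:
                val += float(np.sum(np.log(np.clip(p[sl], 1e-300, None))))
            return -val if np.isfinite(val) else 1e12

        best_val, best_z, ok = np.inf, None, False
        for s in range(config.n_starts):
            z0 = tr.random_start(rng)
            try:
                res = minimize(
                    neg, z0, method="L-BFGS-B",
                    options={"maxiter": config.maxiter, "ftol": config.tol},
                )
            except (ValueError, FloatingPointError):  # pragma: no cover
                continue
            if res.fun < best_val:
                best_val, best_z = res.fun, res.x
                ok = ok or bool(res.success)
        if best_z is None:
            fits.append(
                WindowFit(window, graph.default_params(), names, -np.inf, {}, False)
            )
            continue
        params = tr.to_natural(best_z)
        fits.append(
            WindowFit(
                window,
                params,
                names,
                objective(params, X, window, graph, lam=config.lam),
                graph.decompose(params) if graph.events else {},
                ok,
            )
        )
    return fits


def variance_decomposition(
    fits: WindowFit | list[WindowFit], graph: AdmixtureGraph | None = None
) -> pd.DataFrame:
    """Tidy table of per-window (or aggregated) variance shares.

    For a list of window fits, rows are aggregated per admixed population by
    SNP-count-weighted mean over windows; every row's shares sum to one.
    """
    if isinstance(fits, WindowFit):
        rows = []
        for target, shares in fits.decomposition.items():
            row = {"target": target}
            row.update({(k if k != "__own__" else "own"): v for k, v in shares.items()})
            rows.append(row)
        return pd.DataFrame(rows).set_index("target")
    acc: dict[str, dict[str, float]] = {}
    wsum: dict[str, float] = {}
    for fit in fits:
        if not fit.decomposition:
            continue
        wgt = fit.window.n_snps
        for target, shares in fit.decomposition.items():
            slot = acc.setdefault(target, {})
            for k, v in shares.items():
                slot[k] = slot.get(k, 0.0) + wgt * v
            wsum[target] = wsum.get(target, 0.0) + wgt
    rows = []
    for target, shares in acc.items():
        row = {"target": target}
        row.update(
            {(k if k != "__own__" else "own"): v / wsum[target] for k, v in shares.items()}
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("target") if rows else pd.DataFrame()


def compare_hypotheses(fits_by_hypothesis: dict[str, tuple[AdmixtureGraph, list[WindowFit]]]) -> pd.DataFrame:
    """Rank migration hypotheses by a BIC-type total score (higher better):
    ``2 sum_w objective_w - k log(n_windows * n_pairs)``.

    Also reports ``L = -sum objective`` (lower better) for readers used to
    the negated convention.
    """
    rows = []
    for name, (graph, fits) in fits_by_hypothesis.items():
        total = float(sum(f.objective for f in fits))
        n_windows = len(fits)
        p = len(graph.pop_ids)
        n_pairs = p * (p - 1) // 2
        k = graph.n_params
        n_eff = max(n_windows * n_pairs, 1)
        rows.append(
            {
                "hypothesis": name,
                "k": k,
                "n_windows": n_windows,
                "total_objective": total,
                "L": -total,
                "score": 2 * total - k * np.log(n_eff),
            }
        )
    return (
        pd.DataFrame(rows).sort_values("score", ascending=False).reset_index(drop=True)
    )


_EVENT_RE = re.compile(r"^\s*(\S+)\s*<-\s*(.+)$")


def parse_hypothesis(text: str) -> AdmixtureGraph:
    """Parse a hypothesis file: first non-comment line is the base tree in
    Newick; each following line ``target <- source1, source2[, ...]`` adds an
    admixture event in order."""
    newick = None
    events: list[AdmixtureEvent] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if newick is None:
            newick = line
            continue
        m = _EVENT_RE.match(line)
        if not m:
            raise ValueError(f"cannot parse event line: {line!r}")
        target = m.group(1)
        # a source may carry a ":hint" suffix (ignored; weights are fitted)
        sources = [s.strip().split(":")[0] for s in m.group(2).split(",") if s.strip()]
        events.append(AdmixtureEvent(target, sources))
    if newick is None:
        raise ValueError("hypothesis file holds no tree")
    return AdmixtureGraph(newick, events)
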