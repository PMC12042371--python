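"""Time-stratified likelihood, ML fitting, model selection and ancestral ranges.

The central object is :class:`RangeEvolutionModel`, built from a dated
tree, observed tip ranges, a cladogenesis family and a dispersal
scenario.  Its :meth:`~RangeEvolutionModel.fit` returns a
:class:`RangeEvolutionResults` carrying the ML rates, log-likelihood,
small-sample AIC and a ``summary()`` table; ancestral range marginals
hang off the results object.

The likelihood is Felsenstein pruning over the range state space.  Tip
vectors are indicators of the observed ranges.  Along each branch the
conditional likelihoods pass through the product of per-segment
transition matrices ``expm(Q_s * dt)``, one per time stratum crossed.
At each internal node the two daughter vectors combine through the
cladogenetic event table:

    L(R) = sum_events  p(R -> (R1, R2)) * L_left(R1) * L_right(R2)

and at the root the likelihood is averaged over a prior on the root
range (uniform over non-null states by default).  Per-node rescaling
guards against underflow on deep trees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .chronogram import Chronogram, Node, slice_branch
from .decmodels import (
    J_MAX,
    BiogeoParams,
    CladoTable,
    ModelSpec,
    build_rate_matrix,
    cladogenesis_table,
    transition_matrix,
)
from .rangespace import Geography, StateSpace
from .scenarios import DispersalScenario, build_scenario

__all__ = [
    "RangeEvolutionModel",
    "RangeEvolutionResults",
    "log_likelihood",
    "fit_ml",
    "model_weights",
    "run_model_grid",
    "ancestral_ranges",
    "aicc",
]

_NEG_INF = float("-inf")

logger = logging.getLogger(__name__)

#: Optimizer bounds (natural scale) and deterministic starting points.
D_BOUNDS = (1e-12, 5.0)
E_BOUNDS = (1e-12, 5.0)
J_BOUNDS = (1e-5, J_MAX)
STARTS_DE = (1e-3, 1e-2, 1e-1)
STARTS_J = (1e-4, 0.5, 2.0)


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample AIC: ``-2 lnL + 2k + 2k(k+1)/(n-k-1)``, n = tip count."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * lnL + 2 * k + 2 * k * (k + 1) / (n - k - 1)


class RangeEvolutionModel:
    """DEC-family range evolution on a chronogram under a dispersal scenario.

    Parameters
    ----------
    tree : Chronogram
        Ultrametric dated tree; tip labels must appear in ``geography``.
    geography : Geography
        Observed tip ranges over the state space to use.
    model : ModelSpec or str
        Cladogenesis family, e.g. ``"DEC"`` or ``"DIVALIKE+J"``.
    scenario : DispersalScenario, optional
        Time-stratified dispersal multipliers.  Defaults to a null
        (all-ones) scenario over a single stratum covering the tree.
    root_prior : {"uniform"} or array
        Prior over root ranges; the default is uniform over non-null
        states.  An explicit probability vector over states may be given.
    """

    def __init__(
        self,
        tree: Chronogram,
        geography: Geography,
        model: ModelSpec | str = "DEC",
        scenario: Optional[DispersalScenario] = None,
        root_prior="uniform",
    ):
        self.tree = tree
        self.geography = geography
        self.space: StateSpace = geography.space
        self.spec = ModelSpec.from_name(model) if isinstance(model, str) else model
        if scenario is None:
            from .scenarios import TimeStratum

            span = max(tree.root_age * 1.05, tree.root_age + 1.0)
            scenario = build_scenario(
                "null",
                [a.name for a in self.space.areas],
                strata=(TimeStratum(0, 0.0, span),),
            )
        if tuple(scenario.area_names) != tuple(a.name for a in self.space.areas):
            raise ValueError("scenario areas must match the state-space areas")
        if tree.root_age >= scenario.oldest_bound:
            raise ValueError(
                f"tree root age {tree.root_age} reaches beyond the oldest "
                f"stratum bound {scenario.oldest_bound}"
            )
        self.scenario = scenario
        missing = set(tree.tip_labels) - set(geography.taxa)
        if missing:
            raise ValueError(f"tips without geography: {sorted(missing)}")

        S = self.space.n_states
        if isinstance(root_prior, str):
            if root_prior != "uniform":
                raise ValueError(f"unknown root prior {root_prior!r}")
            pi = np.full(S, 1.0 / (S - 1))
            pi[0] = 0.0
        else:
            pi = np.asarray(root_prior, dtype=float)
            if pi.shape != (S,) or abs(pi.sum() - 1) > 1e-9 or np.any(pi < 0):
                raise ValueError("root prior must be a probability vector over states")
        self.root_prior = pi

        # postorder bookkeeping: node list, per-node branch segments
        self._nodes: list[Node] = list(tree.postorder())
        self._node_id = {id(n): i for i, n in enumerate(self._nodes)}
        bnds = scenario.boundaries
        self._segments = {}
        for n in self._nodes:
            if n.parent is not None and n.branch_length > 0:
                self._segments[id(n)] = slice_branch(
                    n.parent.age, n.age, bnds, scenario.oldest_bound
                )
            else:
                self._segments[id(n)] = []
        self._clado_cache: dict[float, CladoTable] = {}

    # -- model internals ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return self.tree.n_tips

    def _clado(self, j: float) -> CladoTable:
        key = float(j)
        if key not in self._clado_cache:
            self._clado_cache[key] = cladogenesis_table(self.space, self.spec, key)
        return self._clado_cache[key]

    def _branch_matrices(self, params: BiogeoParams) -> dict[int, np.ndarray]:
        """Transition matrix for the branch above each node (rootward product)."""
        Qs = [
            build_rate_matrix(self.space, params, m)
            for m in self.scenario.multipliers
        ]
        pcache: dict[tuple[int, float], np.ndarray] = {}

        def seg_matrix(stratum: int, dt: float) -> np.ndarray:
            key = (stratum, round(dt, 12))
            if key not in pcache:
                pcache[key] = transition_matrix(Qs[stratum], dt)
            return pcache[key]

        mats: dict[int, np.ndarray] = {}
        eye = np.eye(self.space.n_states)
        for n in self._nodes:
            if n.parent is None:
                continue
            segs = self._segments[id(n)]
            if not segs:
                mats[id(n)] = eye
                continue
            M = seg_matrix(segs[0].stratum_index, segs[0].duration)
            for seg in segs[1:]:
                M = M @ seg_matrix(seg.stratum_index, seg.duration)
            mats[id(n)] = M
        return mats

    def _down_pass(self, params: BiogeoParams):
        """Pruning pass; returns (lnL, down, up_messages, branch matrices).

        ``down[id(n)]`` is the rescaled conditional-likelihood vector at
        node n (post-cladogenesis for internal nodes); ``up_messages``
        holds the branch-top vectors ``M_n @ down[n]`` needed both for
        the parent combination and for ancestral marginals.
        """
        clado = self._clado(params.j if self.spec.with_j else 0.0)
        mats = self._branch_matrices(params)
        S = self.space.n_states
        down: dict[int, np.ndarray] = {}
        branch_top: dict[int, np.ndarray] = {}
        log_scale = 0.0
        for n in self._nodes:
            if n.is_tip:
                v = np.zeros(S)
                v[self.space.index_of(self.geography[n.label])] = 1.0
            else:
                cl, cr = n.children
                ul = branch_top[id(cl)]
                ur = branch_top[id(cr)]
                contrib = clado.prob * ul[clado.left_idx] * ur[clado.right_idx]
                v = np.bincount(clado.anc_idx, weights=contrib, minlength=S)
            scale = v.max()
            if scale <= 0 or not np.isfinite(scale):
                return _NEG_INF, down, branch_top, mats
            v = v / scale
            log_scale += math.log(scale)
            down[id(n)] = v
            if n.parent is not None:
                branch_top[id(n)] = mats[id(n)] @ v
        lik = float(self.root_prior @ down[id(self.tree.root)])
        if lik <= 0:
            return _NEG_INF, down, branch_top, mats
        return math.log(lik) + log_scale, down, branch_top, mats

    # -- public API ----------------------------------------------------------

    def loglike(self, params: BiogeoParams | Sequence[float]) -> float:
        """Log-likelihood at the given (d, e[, j])."""
        params = self._as_params(params)
        lnL, *_ = self._down_pass(params)
        return lnL

    def _as_params(self, params) -> BiogeoParams:
        if isinstance(params, BiogeoParams):
            if not self.spec.with_j and params.j != 0:
                raise ValueError(f"{self.spec.name} has no founder-event parameter")
            return params
        vals = list(params)
        if self.spec.with_j:
            d, e, j = vals
        else:
            (d, e), j = vals[:2], 0.0
        return BiogeoParams(d=d, e=e, j=j)

    def fit(self, starts: Optional[Iterable[Sequence[float]]] = None) -> "RangeEvolutionResults":
        """Maximize the likelihood over (d, e[, j]) by bounded quasi-Newton.

        Deterministic multi-start: three starting points spanning three
        orders of magnitude in the rates; the optimizer runs on log10
        scale so the bounds (d, e in [1e-12, 5]; j in [1e-5, 3]) behave
        uniformly.  Non-convergence is flagged on the result rather than
        raised.
        """
        with_j = self.spec.with_j
        if starts is None:
            starts = [
                (v, v, sj) if with_j else (v, v)
                for v, sj in zip(STARTS_DE, STARTS_J)
            ]
        bounds = [D_BOUNDS, E_BOUNDS] + ([J_BOUNDS] if with_j else [])
        log_bounds = [(math.log10(lo), math.log10(hi)) for lo, hi in bounds]

        def neg_loglike(log_theta: np.ndarray) -> float:
            theta = 10.0 ** np.asarray(log_theta)
            lnL = self.loglike(theta)
            return 1e10 if lnL == _NEG_INF else -lnL

        best = None
        any_converged = False
        for start in starts:
            x0 = np.log10(np.asarray(start, dtype=float))
            res = minimize(
                neg_loglike, x0, method="L-BFGS-B", bounds=log_bounds,
                options={"maxiter": 500},
            )
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        theta = 10.0 ** best.x
        params = self._as_params(theta)
        lnL = -best.fun if best.fun < 1e10 else _NEG_INF
        k = self.spec.n_free_params
        if not np.isfinite(lnL):
            crit = float("inf")
        elif self.n_tips - k - 1 <= 0:
            crit = float("nan")  # AICc undefined for so few tips
        else:
            crit = aicc(lnL, k, self.n_tips)
        return RangeEvolutionResults(
            model=self,
            params=params,
            llf=lnL,
            k=k,
            aicc=crit,
            converged=any_converged,
        )

    def ancestral_state_probabilities(self, params: BiogeoParams) -> pd.DataFrame:
        """Marginal range probabilities at every internal node.

        Combines the tipward (pruning) partial likelihoods with rootward
        partials computed in a preorder pass, so each marginal conditions
        on all tip data.  Rows are internal node ids (see
        :meth:`node_table`), columns the state labels; each row sums to 1.
        """
        params = self._as_params(params)
        lnL, down, branch_top, mats = self._down_pass(params)
        if lnL == _NEG_INF:
            raise ValueError("data have zero likelihood under these parameters")
        clado = self._clado(params.j if self.spec.with_j else 0.0)
        S = self.space.n_states
        up: dict[int, np.ndarray] = {id(self.tree.root): self.root_prior.copy()}
        rows = {}
        for n in self.tree.preorder():
            if n.is_tip:
                continue
            u_n = up[id(n)]
            marg = u_n * down[id(n)]
            total = marg.sum()
            if total <= 0:
                raise ValueError("zero marginal encountered; inconsistent data")
            rows[self._node_id[id(n)]] = marg / total
            cl, cr = n.children
            for child, sib in ((cl, cr), (cr, cl)):
                # message through the cladogenesis event, summing the
                # sibling side out:  W[anc, child_state] = sum p * u_sib
                w = clado.prob * branch_top[id(sib)][clado.right_idx]
                W = np.zeros((S, S))
                np.add.at(W, (clado.anc_idx, clado.left_idx), w)
                up_top = W.T @ u_n
                u_child = mats[id(child)].T @ up_top
                scale = u_child.max()
                if scale > 0:
                    u_child = u_child / scale
                up[id(child)] = u_child
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.columns = [self.space.range_label(s) for s in self.space.states]
        return df.sort_index()

    def node_table(self) -> pd.DataFrame:
        """Internal node ids with ages and two descendant tips that define them."""
        rows = []
        for n in self.tree.preorder():
            if n.is_tip:
                continue
            left_tips = _subtree_tip_labels(n.children[0])
            right_tips = _subtree_tip_labels(n.children[1])
            rows.append(
                {
                    "node_id": self._node_id[id(n)],
                    "age_mya": n.age,
                    "example_tip_left": left_tips[0],
                    "example_tip_right": right_tips[0],
                    "n_descendants": len(left_tips) + len(right_tips),
                }
            )
        return pd.DataFrame(rows).set_index("node_id").sort_index()

    def node_id_of(self, node: Node) -> int:
        return self._node_id[id(node)]


def _subtree_tip_labels(root: Node) -> list[str]:
    out, stack = [], [root]
    while stack:
        node = stack.pop()
        if node.is_tip:
            out.append(node.label)
        else:
            stack.extend(reversed(node.children))
    return out


@dataclass
class RangeEvolutionResults:
    """Fitted rates, fit statistics and derived quantities for one model."""

    model: RangeEvolutionModel
    params: BiogeoParams
    llf: float
    k: int
    aicc: float
    converged: bool
    delta_aicc: Optional[float] = None
    aicc_wt: Optional[float] = None

    @property
    def model_name(self) -> str:
        return self.model.spec.name

    @property
    def scenario_name(self) -> str:
        return self.model.scenario.name

    @property
    def d(self) -> float:
        return self.params.d

    @property
    def e(self) -> float:
        return self.params.e

    @property
    def j(self) -> float:
        return self.params.j if self.model.spec.with_j else 0.0

    def ancestral_ranges(self) -> pd.DataFrame:
        """Marginal range probabilities at internal nodes under the fit."""
        return self.model.ancestral_state_probabilities(self.params)

    def as_row(self) -> dict:
        return {
            "model": self.model_name,
            "scenario": self.scenario_name,
            "d": self.d,
            "e": self.e,
            "j": self.j,
            "lnL": self.llf,
            "k": self.k,
            "AICc": self.aicc,
            "delta_AICc": self.delta_aicc,
            "AICc_wt": self.aicc_wt,
            "converged": self.converged,
        }

    def summary(self) -> str:
        lines = [
            "Range evolution model fit",
            "=" * 46,
            f"{'Model:':<22}{self.model_name}",
            f"{'Scenario:':<22}{self.scenario_name}",
            f"{'Tips:':<22}{self.model.n_tips}",
            f"{'Areas:':<22}{self.model.space.n_areas}"
            f" (max range size {self.model.space.max_range_size})",
            f"{'States:':<22}{self.model.space.n_states}",
            "-" * 46,
            f"{'dispersal d:':<22}{self.d:.6g}  / lineage / my",
            f"{'extirpation e:':<22}{self.e:.6g}  / area / my",
        ]
        if self.model.spec.with_j:
            lines.append(f"{'founder-event j:':<22}{self.j:.6g}")
        lines += [
            f"{'log-likelihood:':<22}{self.llf:.4f}",
            f"{'free parameters k:':<22}{self.k}",
            f"{'AICc:':<22}{self.aicc:.4f}",
            f"{'converged:':<22}{self.converged}",
            "=" * 46,
        ]
        return "\n".join(lines)


# -- functional wrappers ------------------------------------------------------


def log_likelihood(
    tree: Chronogram,
    geo: Geography,
    spec: ModelSpec | str,
    scenario: Optional[DispersalScenario],
    params: BiogeoParams,
) -> float:
    """Pruning log-likelihood of the tip ranges under one parameter set."""
    return RangeEvolutionModel(tree, geo, spec, scenario).loglike(params)


def fit_ml(
    tree: Chronogram,
    geo: Geography,
    spec: ModelSpec | str,
    scenario: Optional[DispersalScenario] = None,
) -> RangeEvolutionResults:
    """Fit one model by maximum likelihood; see :meth:`RangeEvolutionModel.fit`."""
    return RangeEvolutionModel(tree, geo, spec, scenario).fit()


def model_weights(results: Sequence[RangeEvolutionResults]) -> list[RangeEvolutionResults]:
    """Fill delta-AICc and Akaike weights; sort ascending by AICc.

    Ties are broken by fewer free parameters, then by model name.
    """
    if not results:
        raise ValueError("at least one result is required")
    finite = [r.aicc for r in results if np.isfinite(r.aicc)]
    best = min(finite) if finite else float("inf")
    rel = []
    for r in results:
        r.delta_aicc = r.aicc - best
        rel.append(math.exp(-r.delta_aicc / 2) if np.isfinite(r.delta_aicc) else 0.0)
    total = sum(rel)
    for r, w in zip(results, rel):
        r.aicc_wt = w / total if total > 0 else float("nan")
    return sorted(
        results,
        key=lambda r: (r.aicc, r.k, f"{r.scenario_name} {r.model_name}"),
    )


def run_model_grid(
    tree: Chronogram,
    geo: Geography,
    scenarios: Mapping[str, DispersalScenario],
    model_names: Sequence[str] = ("DEC", "DEC+J", "DIVALIKE", "DIVALIKE+J",
                                  "BAYAREALIKE", "BAYAREALIKE+J"),
) -> pd.DataFrame:
    """Fit every scenario x model combination and rank by AICc.

    Four scenarios crossed with the three base families and their +J
    variants give the full 24-model comparison.  A failure in one model
    is recorded in its row; the grid always completes.
    """
    results: list[RangeEvolutionResults] = []
    failures: list[dict] = []
    for scen_name, scenario in scenarios.items():
        for model_name in model_names:
            try:
                res = fit_ml(tree, geo, model_name, scenario)
                logger.info(
                    "fit %s %s: lnL=%.4f d=%.4g e=%.4g j=%.4g converged=%s",
                    scen_name, model_name, res.llf, res.d, res.e, res.j,
                    res.converged,
                )
                results.append(res)
            except Exception as exc:  # recorded per-row, grid completes
                failures.append(
                    {
                        "model": model_name,
                        "scenario": scen_name,
                        "lnL": float("nan"),
                        "AICc": float("inf"),
                        "error": str(exc),
                    }
                )
    ranked = model_weights(results) if results else []
    rows = [r.as_row() for r in ranked] + failures
    df = pd.DataFrame(rows)
    if "error" not in df.columns:
        df["error"] = ""
    df["error"] = df["error"].fillna("")
    return df


def ancestral_ranges(
    tree: Chronogram,
    geo: Geography,
    spec: ModelSpec | str,
    scenario: Optional[DispersalScenario],
    params: BiogeoParams,
) -> pd.DataFrame:
    """Marginal range probabilities at internal nodes for fitted parameters."""
    return RangeEvolutionModel(tree, geo, spec, scenario).ancestral_state_probabilities(params)
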