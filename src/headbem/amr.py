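"""Adaptive mesh refinement driven by facet charge and electrode stability.

Thin gaps between conductivity interfaces concentrate induced charge and
make the coarse collocation solution inaccurate exactly where it matters.
The AMR loop repairs this adaptively:

1. solve for the surface charge density;
2. rank refinable facets by the cost C_m = |rho_m| * A_m (total charge
   magnitude in the triangle);
3. subdivide the top fraction (default 1 %) into four congruent children;
4. re-solve and sample the electrode voltages V_k on the (never refined)
   skin interface;
5. stop when the relative electrode-voltage change
   ||V_k - V_{k-1}|| / ||V_{k-1}|| drops below the threshold (default 1 %),
   or after ``max_steps`` refinements.

The skin interface is the observation region and is excluded from
refinement, so electrode facet assignments stay valid across steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .forward import BemOperator, ChargeSolution, EEGSample, electrode_voltages, solve_charges
from .headmodel import HeadModel
from .mesh import subdivide_facets

__all__ = ["AMRState", "facet_costs", "select_top_fraction", "amr_loop"]


@dataclass
class AMRState:
    """Full history of one adaptive refinement run."""

    step: int
    model: HeadModel
    solution: ChargeSolution
    voltage_history: list = field(default_factory=list)
    rel_change_history: list = field(default_factory=list)
    facet_count_history: list = field(default_factory=list)
    n_selected_history: list = field(default_factory=list)
    converged: bool = False

    @property
    def final_voltages(self) -> EEGSample:
        return self.voltage_history[-1]

    def trace_table(self):
        """Tabular AMR trace (step, facets, selected, rel_change)."""
        import pandas as pd

        steps = list(range(len(self.facet_count_history)))
        return pd.DataFrame(
            {
                "step": steps,
                "facets": self.facet_count_history,
                "selected": self.n_selected_history + [0] * (
                    len(steps) - len(self.n_selected_history)
                ),
                "rel_change": [np.nan] + self.rel_change_history,
            }
        )

    def plot_convergence(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(range(1, len(self.rel_change_history) + 1),
                    self.rel_change_history, "o-")
        ax.axhline(0.01, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("AMR step")
        ax.set_ylabel("relative electrode-voltage change")
        return ax


def facet_costs(solution: ChargeSolution) -> np.ndarray:
    """Per-facet cost |rho_m| * A_m, zeroed on non-refinable interfaces."""
    model = solution.model
    costs = np.abs(solution.rho) * model.facet_areas
    costs[~model.refinable_facet_mask] = 0.0
    return costs


def select_top_fraction(costs: np.ndarray, fraction: float,
                        refinable_mask: np.ndarray | None = None) -> np.ndarray:
    """Flat indices of the ceil(fraction * M_refinable) largest costs.

    Only refinable facets compete and count toward the pool size.  Ties are
    broken toward the lower facet index, making selection deterministic.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    costs = np.asarray(costs, float)
    if refinable_mask is None:
        refinable_mask = np.ones(len(costs), dtype=bool)
    pool = np.flatnonzero(refinable_mask)
    if pool.size == 0:
        return np.empty(0, dtype=np.int64)
    k = int(np.ceil(fraction * pool.size))
    order = np.lexsort((pool, -costs[pool]))  # cost desc, then index asc
    return np.sort(pool[order[:k]])


def _refine_model(
    model: HeadModel, flat_indices: np.ndarray, rho: np.ndarray
) -> tuple[HeadModel, np.ndarray, np.ndarray]:
    """Subdivide the selected facets; prolong rho onto the children.

    Returns (refined model, prolonged rho, new_to_old flat index map with
    -1 marking newly created child facets).
    """
    new_model = model
    rho_parts = []
    map_parts = []
    for i in range(model.n_interfaces):
        s = model.interface_slice(i)
        local = flat_indices[(flat_indices >= s.start) & (flat_indices < s.stop)] - s.start
        rho_i = rho[s]
        if local.size == 0:
            rho_parts.append(rho_i)
            map_parts.append(np.arange(s.start, s.stop, dtype=np.int64))
            continue
        mesh = model.interfaces[i]
        refined = subdivide_facets(mesh, local)
        new_model = new_model.with_refined_interface(i, refined)
        keep = np.ones(mesh.n_facets, dtype=bool)
        keep[local] = False
        # children keep the parent's density (a charge-conserving
        # prolongation for 4 congruent equal-area children)
        rho_parts.append(np.concatenate([rho_i[keep], np.repeat(rho_i[np.sort(local)], 4)]))
        map_parts.append(np.concatenate([
            s.start + np.flatnonzero(keep),
            np.full(4 * local.size, -1, dtype=np.int64),
        ]))
    return new_model, np.concatenate(rho_parts), np.concatenate(map_parts)


def amr_loop(
    model: HeadModel,
    source,
    electrodes,
    threshold: float = 0.01,
    max_steps: int = 15,
    fraction: float = 0.01,
    tol: float = 1e-6,
    backend: str | None = None,
    near_factor: float = 3.0,
    method: str = "auto",
) -> AMRState:
    """Run the adaptive refinement loop until electrode voltages stabilize.

    Step 0 is the un-refined solve; the first stopping ratio compares
    steps 1 and 0, so at least one refinement is always attempted unless
    the threshold exceeds that first ratio.  Raises nothing on hitting
    ``max_steps``; a truncation warning is emitted and the state returned
    with ``converged=False``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")

    def _solve(mdl, x0=None, reuse=None):
        op = BemOperator(mdl, backend, near_factor, deflate=True, reuse=reuse)
        return solve_charges(mdl, source, tol=tol, method=method, x0=x0,
                             operator=op)

    sol = _solve(model)
    state = AMRState(step=0, model=model, solution=sol)
    V = electrode_voltages(sol, electrodes)
    state.voltage_history.append(V)
    state.facet_count_history.append(model.n_facets)

    for step in range(1, max_steps + 1):
        costs = facet_costs(state.solution)
        sel = select_top_fraction(costs, fraction,
                                  state.model.refinable_facet_mask)
        new_model, rho0, new_to_old = _refine_model(
            state.model, sel, state.solution.rho
        )
        try:
            sol = _solve(new_model, x0=rho0,
                         reuse=(state.solution.operator, new_to_old))
        except Exception as exc:
            raise type(exc)(f"AMR step {step}: {exc}") from exc
        V_new = electrode_voltages(sol, electrodes)
        prev = state.voltage_history[-1].voltages
        ratio = float(
            np.linalg.norm(V_new.voltages - prev) / np.linalg.norm(prev)
        )
        state.step = step
        state.model = new_model
        state.solution = sol
        state.voltage_history.append(V_new)
        state.rel_change_history.append(ratio)
        state.facet_count_history.append(new_model.n_facets)
        state.n_selected_history.append(int(sel.size))
        if ratio < threshold:
            state.converged = True
            break
    if not state.converged:
        warnings.warn(
            f"AMR loop truncated at max_steps={max_steps} with last relative "
            f"change {state.rel_change_history[-1]:.3e} >= {threshold}",
            RuntimeWarning,
        )
    return state
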