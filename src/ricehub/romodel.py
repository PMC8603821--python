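"""Uncertain many-to-many location-routing model and its robust counterpart.

The deterministic model chooses food-hub sites x_j in {0,1}, hub capacities
P_cj >= 0 and distribution ratios y_ckj (producer k -> hub j) and w_cji
(hub j -> demand area i), both in [0,1], subject to

    sum_k f_ck y_ckj = P_cj          (hub inflow balance)
    sum_i d_ci w_cji = P_cj          (hub outflow balance)
    sum_j y_ckj <= 1,  sum_j w_cji <= 1
    y_ckj <= x_j,      w_cji <= x_j

with two objectives: maximize the selling-price-weighted tons delivered,
sum_ci v_ci d_ci sum_j w_cji, and minimize total cost

    h sum_j x_j + sum_cj q_c P_cj + sum_cji b_ji d_ci w_cji
                + sum_ckj b_kj f_ck y_ckj.

Production capacities f (and optionally demands d) are uncertain inside
polyhedral sets {zeta : M zeta <= q}.  The robust counterpart replaces each
uncertainty-affected constraint by its worst case over the set via LP
duality: for each balance constraint a nonnegative dual vector v with
M' v = (loading of the decision variables) whose contribution q' v equals
the worst-case deviation; the cost objective gains an epigraph variable z
with matching dual blocks.  With the singleton set {0} the robust
counterpart reduces exactly to the nominal model.

Multi-objective handling is lexicographic by default: stage 1 maximizes
fulfillment, stage 2 minimizes cost with the stage-1 value fixed within a
relative tolerance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .uncertainty import PolyhedralSet

__all__ = [
    "InstanceData",
    "UncertaintyAttachment",
    "UncertainInstance",
    "NetworkSolution",
    "build_nominal",
    "build_rc",
    "scalarize",
    "solve",
    "verify_robustness",
    "report_tables",
    "attach_capacity_sets",
    "interval_set",
    "singleton_set",
    "enumerate_vertices",
]


# ---------------------------------------------------------------------------
# instance data


@dataclass
class InstanceData:
    """Sets and nominal parameters of the location-routing instance.

    The paper's handling cost and the polyhedron right-hand side share the
    symbol q; here they are ``handling_cost`` and ``PolyhedralSet.q``.
    """

    commodities: list[str]
    demand_areas: list[str]  # I
    hub_sites: list[str]  # J
    producer_areas: list[str]  # K
    demand: np.ndarray  # (C, I) ton/day
    price: np.ndarray  # (C, I) Rp/ton
    capacity: np.ndarray  # (C, K) ton/day
    cost_hub_to_demand: np.ndarray  # (J, I) Rp/ton
    cost_producer_to_hub: np.ndarray  # (K, J) Rp/ton
    handling_cost: np.ndarray  # (C,) Rp/ton
    hub_cost: float  # Rp/unit

    def __post_init__(self):
        self.demand = np.asarray(self.demand, dtype=float)
        self.price = np.asarray(self.price, dtype=float)
        self.capacity = np.asarray(self.capacity, dtype=float)
        self.cost_hub_to_demand = np.asarray(self.cost_hub_to_demand, dtype=float)
        self.cost_producer_to_hub = np.asarray(self.cost_producer_to_hub, dtype=float)
        self.handling_cost = np.asarray(self.handling_cost, dtype=float).ravel()
        C, I, J, K = self.n_c, self.n_i, self.n_j, self.n_k
        if not (C and I and J and K):
            raise ValueError("all sets must be nonempty")
        checks = {
            "demand": (self.demand.shape, (C, I)),
            "price": (self.price.shape, (C, I)),
            "capacity": (self.capacity.shape, (C, K)),
            "cost_hub_to_demand": (self.cost_hub_to_demand.shape, (J, I)),
            "cost_producer_to_hub": (self.cost_producer_to_hub.shape, (K, J)),
            "handling_cost": (self.handling_cost.shape, (C,)),
        }
        for name, (got, want) in checks.items():
            if got != want:
                raise ValueError(f"{name} has shape {got}, expected {want}")
        for name in ("demand", "price", "capacity", "cost_hub_to_demand",
                     "cost_producer_to_hub", "handling_cost"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")
        if self.hub_cost < 0:
            raise ValueError("hub_cost must be nonnegative")

    @property
    def n_c(self):
        return len(self.commodities)

    @property
    def n_i(self):
        return len(self.demand_areas)

    @property
    def n_j(self):
        return len(self.hub_sites)

    @property
    def n_k(self):
        return len(self.producer_areas)


@dataclass
class UncertaintyAttachment:
    """One uncertain parameter group tied to a polyhedral set.

    kind "capacity": coords are (c, k) indices into f_ck; kind "demand":
    coords are (c, i) indices into d_ci.  Column l of the set's M matrix is
    the uncertainty coordinate of coords[l]; the realized parameter is
    nominal + zeta_l.
    """

    kind: str  # "capacity" | "demand"
    pset: PolyhedralSet
    coords: list[tuple[int, int]]

    def __post_init__(self):
        if self.kind not in ("capacity", "demand"):
            raise ValueError(f"unsupported uncertainty kind {self.kind!r}")
        if len(self.coords) != self.pset.dim:
            raise ValueError("coords length must equal the set dimension")

    def coordinate_bounds(self) -> np.ndarray:
        """(L, 2) array of [min, max] of each coordinate over the set."""
        verts = enumerate_vertices(self.pset)
        return np.column_stack([verts.min(axis=0), verts.max(axis=0)])


@dataclass
class UncertainInstance:
    base: InstanceData
    attachments: list[UncertaintyAttachment] = field(default_factory=list)

    def worst_case_capacity(self) -> np.ndarray:
        """Nominal capacity plus the most adverse (lowest) deviation per (c,k)."""
        f = self.base.capacity.copy()
        for att in self.attachments:
            if att.kind != "capacity":
                continue
            lo = att.coordinate_bounds()[:, 0]
            for l, (c, k) in enumerate(att.coords):
                f[c, k] += lo[l]
        return np.maximum(f, 0.0)


def interval_set(lo: float, hi: float) -> PolyhedralSet:
    """1-D polyhedral set {u : lo <= u <= hi}."""
    if lo > hi:
        raise ValueError("lo > hi")
    return PolyhedralSet(M=np.array([[1.0], [-1.0]]), q=np.array([hi, -lo]))


def singleton_set(dim: int = 1) -> PolyhedralSet:
    """The singleton {0}: the robust counterpart then equals the nominal model."""
    eye = np.eye(dim)
    return PolyhedralSet(M=np.vstack([eye, -eye]), q=np.zeros(2 * dim))


def attach_capacity_sets(
    instance: InstanceData,
    region_sets: dict[str, PolyhedralSet],
    t_star: float,
    commodity: int | str = 0,
) -> UncertainInstance:
    """Slice per-region 2-D (t, u) sets at planning day t_star into scalar
    capacity intervals and attach them to the instance.

    t_star is the planning day whose production uncertainty the (per-period)
    optimizer faces; each region's interval is {u : (t_star, u) in set}.
    """
    c = instance.commodities.index(commodity) if isinstance(commodity, str) else commodity
    atts = []
    for region, pset in region_sets.items():
        k = instance.producer_areas.index(region)
        lo, hi = pset.slice_u(t_star)
        # production cannot go below zero tons
        lo = max(lo, -instance.capacity[c, k])
        atts.append(UncertaintyAttachment("capacity", interval_set(lo, hi), [(c, k)]))
    return UncertainInstance(base=instance, attachments=atts)


def _assert_bounded(pset: PolyhedralSet) -> None:
    """Raise if {M zeta <= q} is unbounded (checked coordinate-wise by LP)."""
    from scipy.optimize import linprog

    for l in range(pset.dim):
        for sign in (1.0, -1.0):
            c = np.zeros(pset.dim)
            c[l] = sign
            res = linprog(c, A_ub=pset.M, b_ub=pset.q, bounds=[(None, None)] * pset.dim)
            if res.status == 3:  # unbounded
                raise ValueError("uncertainty set is unbounded; duality requires boundedness")
            if res.status == 2:
                raise ValueError("uncertainty set is empty")


def enumerate_vertices(pset: PolyhedralSet, tol: float = 1e-7) -> np.ndarray:
    """Vertices of a bounded polyhedron by basis enumeration (small dims only)."""
    M, q = pset.M, pset.q
    H, L = M.shape
    verts = []
    for rows in itertools.combinations(range(H), L):
        A = M[list(rows)]
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        v = np.linalg.solve(A, q[list(rows)])
        if np.all(M @ v <= q + tol * np.maximum(1.0, np.abs(q))):
            verts.append(v)
    if not verts:
        raise ValueError("polyhedron has no vertices (empty or unbounded)")
    verts = np.array(verts)
    # deduplicate
    keep = []
    for v in verts:
        if not any(np.allclose(v, w, atol=1e-9 * max(1.0, float(np.abs(v).max()))) for w in keep):
            keep.append(v)
    return np.array(keep)


# ---------------------------------------------------------------------------
# model assembly


class RobustModel:
    """Deterministic MILP encoding of the robust counterpart.

    Variable layout: [x (J, binary) | P (C*J) | y (C*K*J) | w (C*J*I) | z |
    dual blocks].  Dual blocks exist per attachment: balance duals per
    (commodity, hub) and one cost-epigraph dual vector.
    """

    def __init__(self, uinst: UncertainInstance):
        self.uinst = uinst
        inst = uinst.base
        C, I, J, K = inst.n_c, inst.n_i, inst.n_j, inst.n_k
        self.inst = inst

        self.off_x = 0
        self.off_P = J
        self.off_y = self.off_P + C * J
        self.off_w = self.off_y + C * K * J
        self.off_z = self.off_w + C * J * I
        n = self.off_z + 1

        # dual variable blocks
        self._bal_blocks = []  # (att, c, j, offset) balance duals, length H
        self._cost_blocks = []  # (att, offset) cost duals, length H
        for att in uinst.attachments:
            _assert_bounded(att.pset)  # duality needs a bounded set
            H = att.pset.n_rows
            comms = sorted({c for c, _ in att.coords})
            for c in comms:
                for j in range(J):
                    self._bal_blocks.append((att, c, j, n))
                    n += H
            self._cost_blocks.append((att, n))
            n += H
        self.n_vars = n

        self._build_matrices()

    # -- index helpers ----------------------------------------------------
    def ix(self, j):
        return self.off_x + j

    def iP(self, c, j):
        return self.off_P + c * self.inst.n_j + j

    def iy(self, c, k, j):
        return self.off_y + (c * self.inst.n_k + k) * self.inst.n_j + j

    def iw(self, c, j, i):
        return self.off_w + (c * self.inst.n_j + j) * self.inst.n_i + i

    # -- assembly ---------------------------------------------------------
    def _build_matrices(self):
        inst = self.inst
        C, I, J, K = inst.n_c, inst.n_i, inst.n_j, inst.n_k
        f, d = inst.capacity, inst.demand
        b_ji, b_kj = inst.cost_hub_to_demand, inst.cost_producer_to_hub

        eq_rows: list[dict[int, float]] = []
        ub_rows: list[dict[int, float]] = []
        ub_rhs: list[float] = []

        cap_atts = [a for a in self.uinst.attachments if a.kind == "capacity"]
        dem_atts = [a for a in self.uinst.attachments if a.kind == "demand"]
        bal_off = {(id(att), c, j): off for att, c, j, off in self._bal_blocks}

        # inflow balance with worst-case dual term: sum_k f y - q'v - P = 0 per (c, j)
        for c in range(C):
            for j in range(J):
                row = {self.iy(c, k, j): f[c, k] for k in range(K) if f[c, k] != 0.0}
                row[self.iP(c, j)] = row.get(self.iP(c, j), 0.0) - 1.0
                for att in cap_atts:
                    if (id(att), c, j) not in bal_off:
                        continue
                    off = bal_off[(id(att), c, j)]
                    for g in range(att.pset.n_rows):
                        if att.pset.q[g] != 0.0:
                            row[off + g] = row.get(off + g, 0.0) - att.pset.q[g]
                eq_rows.append(row)

        # inflow dual link: sum_g M[g,l] v[g] + y_ckj = 0 per capacity attachment, (c,j), l
        for att in cap_atts:
            for c, j, off in (
                (c, j, bal_off[(id(att), c, j)])
                for c in sorted({cc for cc, _ in att.coords})
                for j in range(J)
            ):
                for l, (cc, k) in enumerate(att.coords):
                    if cc != c:
                        continue
                    row = {off + g: att.pset.M[g, l] for g in range(att.pset.n_rows)
                           if att.pset.M[g, l] != 0.0}
                    row[self.iy(c, k, j)] = row.get(self.iy(c, k, j), 0.0) + 1.0
                    eq_rows.append(row)

        # outflow balance with worst-case dual term: sum_i d w - q'v - P = 0 per (c, j)
        for c in range(C):
            for j in range(J):
                row = {self.iw(c, j, i): d[c, i] for i in range(I) if d[c, i] != 0.0}
                row[self.iP(c, j)] = row.get(self.iP(c, j), 0.0) - 1.0
                for att in dem_atts:
                    if (id(att), c, j) not in bal_off:
                        continue
                    off = bal_off[(id(att), c, j)]
                    for g in range(att.pset.n_rows):
                        if att.pset.q[g] != 0.0:
                            row[off + g] = row.get(off + g, 0.0) - att.pset.q[g]
                eq_rows.append(row)

        # outflow dual link: sum_g M[g,l] v[g] + w_cji = 0
        for att in dem_atts:
            for c, j, off in (
                (c, j, bal_off[(id(att), c, j)])
                for c in sorted({cc for cc, _ in att.coords})
                for j in range(J)
            ):
                for l, (cc, i) in enumerate(att.coords):
                    if cc != c:
                        continue
                    row = {off + g: att.pset.M[g, l] for g in range(att.pset.n_rows)
                           if att.pset.M[g, l] != 0.0}
                    row[self.iw(c, j, i)] = row.get(self.iw(c, j, i), 0.0) + 1.0
                    eq_rows.append(row)

        # supply and demand ratio caps
        for c in range(C):
            for k in range(K):
                ub_rows.append({self.iy(c, k, j): 1.0 for j in range(J)})
                ub_rhs.append(1.0)
        for c in range(C):
            for i in range(I):
                ub_rows.append({self.iw(c, j, i): 1.0 for j in range(J)})
                ub_rhs.append(1.0)

        # flows only through opened hubs
        for c in range(C):
            for k in range(K):
                for j in range(J):
                    ub_rows.append({self.iy(c, k, j): 1.0, self.ix(j): -1.0})
                    ub_rhs.append(0.0)
        for c in range(C):
            for j in range(J):
                for i in range(I):
                    ub_rows.append({self.iw(c, j, i): 1.0, self.ix(j): -1.0})
                    ub_rhs.append(0.0)

        # cost epigraph: nominal distribution cost + worst-case dual terms <= z
        cost_row: dict[int, float] = {self.off_z: -1.0}
        for c in range(C):
            for j in range(J):
                for i in range(I):
                    coef = b_ji[j, i] * d[c, i]
                    if coef:
                        cost_row[self.iw(c, j, i)] = cost_row.get(self.iw(c, j, i), 0.0) + coef
                for k in range(K):
                    coef = b_kj[k, j] * f[c, k]
                    if coef:
                        cost_row[self.iy(c, k, j)] = cost_row.get(self.iy(c, k, j), 0.0) + coef
        for att, off in self._cost_blocks:
            for g in range(att.pset.n_rows):
                if att.pset.q[g] != 0.0:
                    cost_row[off + g] = cost_row.get(off + g, 0.0) + att.pset.q[g]
        ub_rows.append(cost_row)
        ub_rhs.append(0.0)

        # cost dual links: sum_g M[g,l] v[g] - (cost loading of the decisions) = 0
        for att, off in self._cost_blocks:
            for l, (c, kk) in enumerate(att.coords):
                row = {off + g: att.pset.M[g, l] for g in range(att.pset.n_rows)
                       if att.pset.M[g, l] != 0.0}
                if att.kind == "capacity":
                    for j in range(J):
                        if b_kj[kk, j]:
                            row[self.iy(c, kk, j)] = row.get(self.iy(c, kk, j), 0.0) - b_kj[kk, j]
                else:  # demand: coordinate (c, i) loads b_ji w_cji
                    for j in range(J):
                        if b_ji[j, kk]:
                            row[self.iw(c, j, kk)] = row.get(self.iw(c, j, kk), 0.0) - b_ji[j, kk]
                eq_rows.append(row)

        self.A_eq = self._to_sparse(eq_rows)
        self.b_eq = np.zeros(len(eq_rows))
        self.A_ub = self._to_sparse(ub_rows)
        self.b_ub = np.array(ub_rhs)

        # objectives
        c1 = np.zeros(self.n_vars)  # fulfillment (to maximize)
        for c in range(C):
            for j in range(J):
                for i in range(I):
                    c1[self.iw(c, j, i)] = inst.price[c, i] * d[c, i]
        c2 = np.zeros(self.n_vars)  # cost (to minimize)
        c2[self.off_z] = 1.0
        for j in range(J):
            c2[self.ix(j)] = inst.hub_cost
        for c in range(C):
            for j in range(J):
                c2[self.iP(c, j)] = inst.handling_cost[c]
        self.c_fulfill = c1
        self.c_cost = c2

        lb = np.zeros(self.n_vars)
        ub = np.full(self.n_vars, np.inf)
        ub[self.off_x : self.off_P] = 1.0  # x
        ub[self.off_y : self.off_z] = 1.0  # y, w
        lb[self.off_z] = -np.inf  # z free
        self.bounds = Bounds(lb, ub)
        integrality = np.zeros(self.n_vars)
        integrality[self.off_x : self.off_P] = 1
        self.integrality = integrality

    def _to_sparse(self, rows: list[dict[int, float]]) -> sp.csr_matrix:
        data, ri, ci = [], [], []
        for r, row in enumerate(rows):
            for c, v in row.items():
                ri.append(r)
                ci.append(c)
                data.append(v)
        return sp.csr_matrix((data, (ri, ci)), shape=(len(rows), self.n_vars))

    # -- solving ----------------------------------------------------------
    def _milp(self, c, extra_ub=None):
        cons = [LinearConstraint(self.A_ub, -np.inf, self.b_ub)]
        if self.A_eq.shape[0]:
            cons.append(LinearConstraint(self.A_eq, self.b_eq, self.b_eq))
        if extra_ub is not None:
            A, hi = extra_ub
            cons.append(LinearConstraint(sp.csr_matrix(A), -np.inf, hi))
        res = milp(
            c=c,
            constraints=cons,
            integrality=self.integrality,
            bounds=self.bounds,
            options={"mip_rel_gap": 1e-9},
        )
        if res.status != 0:
            raise RuntimeError(f"solver failed: {res.message} (status {res.status})")
        return res


@dataclass
class SolvePlan:
    """A scalarized solve strategy over the two objectives."""

    model: RobustModel
    method: str = "lexicographic"
    weight: float = 1.0  # lambda for the weighted method
    stage1_tol: float = 1e-9  # relative slack on the stage-1 value


@dataclass
class NetworkSolution:
    """Opened hubs, capacities, flows and fulfillment of a solved model."""

    instance: InstanceData
    hubs_open: np.ndarray  # (J,) bool
    hub_capacity: np.ndarray  # (C, J) tons
    y: np.ndarray  # (C, K, J)
    w: np.ndarray  # (C, J, I)
    effective_capacity: np.ndarray  # (C, K) worst-case producer capacity
    objective_fulfillment: float  # Rp (price-weighted tons delivered)
    objective_cost: float  # Rp
    status: str = "optimal"

    @property
    def flows_in(self) -> np.ndarray:  # (C, K, J) tons producer -> hub
        return self.effective_capacity[:, :, None] * self.y

    @property
    def flows_out(self) -> np.ndarray:  # (C, J, I) tons hub -> demand area
        return self.instance.demand[:, None, :] * self.w

    @property
    def fulfillment_fraction(self) -> np.ndarray:  # (C, I)
        return self.w.sum(axis=1)


def build_nominal(instance: InstanceData) -> RobustModel:
    """Nominal (certain) model: the robust counterpart with no attachments."""
    return RobustModel(UncertainInstance(base=instance, attachments=[]))


def build_rc(uinst: UncertainInstance) -> RobustModel:
    """Robust counterpart under the instance's polyhedral attachments."""
    return RobustModel(uinst)


def scalarize(model: RobustModel, method: str = "lexicographic", weight: float = 1.0) -> SolvePlan:
    if method not in ("lexicographic", "weighted"):
        raise ValueError(f"unknown scalarization method {method!r}")
    return SolvePlan(model=model, method=method, weight=weight)


def solve(plan: SolvePlan | RobustModel, **kwargs) -> NetworkSolution:
    """Solve a scalarized model and extract the network solution."""
    if isinstance(plan, RobustModel):
        plan = scalarize(plan, **kwargs)
    model = plan.model
    if plan.method == "lexicographic":
        res1 = model._milp(-model.c_fulfill)
        best = -res1.fun
        slack = plan.stage1_tol * max(1.0, abs(best))
        res2 = model._milp(model.c_cost, extra_ub=(-model.c_fulfill[None, :], -(best - slack)))
        xvec = res2.x
        fulfill = float(model.c_fulfill @ xvec)
        cost = float(model.c_cost @ xvec)
    else:
        res = model._milp(-(model.c_fulfill - plan.weight * model.c_cost))
        xvec = res.x
        fulfill = float(model.c_fulfill @ xvec)
        cost = float(model.c_cost @ xvec)

    inst = model.inst
    C, I, J, K = inst.n_c, inst.n_i, inst.n_j, inst.n_k
    x = xvec[model.off_x : model.off_P] > 0.5
    P = xvec[model.off_P : model.off_y].reshape(C, J)
    y = xvec[model.off_y : model.off_w].reshape(C, K, J)
    w = xvec[model.off_w : model.off_z].reshape(C, J, I)
    y = np.clip(y, 0.0, 1.0)
    w = np.clip(w, 0.0, 1.0)
    f_eff = model.uinst.worst_case_capacity()
    return NetworkSolution(
        instance=inst,
        hubs_open=x,
        hub_capacity=P,
        y=y,
        w=w,
        effective_capacity=f_eff,
        objective_fulfillment=fulfill,
        objective_cost=cost,
    )


# ---------------------------------------------------------------------------
# robustness verification and reporting


def verify_robustness(
    solution: NetworkSolution,
    uinst: UncertainInstance,
    n_interior: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
) -> dict:
    """Re-evaluate the uncertain constraints at hull vertices (and sampled
    interior points) of every attachment; report the maximum violation.

    A robust solution must show violation <= solver tolerance; a nominal
    solution exposed to adverse deviations will not.
    """
    inst = solution.instance
    rng = np.random.default_rng(seed)
    max_violation = 0.0
    checks = 0
    for att in uinst.attachments:
        verts = enumerate_vertices(att.pset)
        points = [v for v in verts]
        for _ in range(n_interior):
            lam = rng.dirichlet(np.ones(len(verts)))
            points.append(lam @ verts)
        for u in points:
            if att.kind == "capacity":
                f = inst.capacity.copy()
                for l, (c, k) in enumerate(att.coords):
                    f[c, k] += u[l]
                inflow = np.einsum("ck,ckj->cj", f, solution.y)
                viol = float(np.max(solution.hub_capacity - inflow))
            else:
                d = inst.demand.copy()
                for l, (c, i) in enumerate(att.coords):
                    d[c, i] += u[l]
                outflow = np.einsum("ci,cji->cj", d, solution.w)
                viol = float(np.max(solution.hub_capacity - outflow))
            max_violation = max(max_violation, viol)
            checks += 1
    return {
        "max_violation": max_violation,
        "n_points_checked": checks,
        "robust": max_violation <= tol * max(1.0, float(np.abs(solution.hub_capacity).max(initial=0.0))),
    }


def report_tables(solution: NetworkSolution, commodity: int = 0) -> dict[str, pd.DataFrame]:
    """Solution as three report tables: hubs, producer supply, fulfillment.

    Tons are rounded to 3 decimals, percentages to 2.
    """
    inst = solution.instance
    c = commodity
    open_j = np.flatnonzero(solution.hubs_open)

    hubs = pd.DataFrame(
        {
            "food_hub_location": [inst.hub_sites[j] for j in open_j],
            "capacity_tons": [round(solution.hub_capacity[c, j], 3) for j in open_j],
        }
    )

    rows = []
    flows_in = solution.flows_in
    for k, area in enumerate(inst.producer_areas):
        cap = solution.effective_capacity[c, k]
        for j in open_j:
            qty = flows_in[c, k, j]
            if qty > 1e-9:
                rows.append(
                    {
                        "producer_area": area,
                        "production_capacity_tons": round(cap, 3),
                        "supplied_to_hub": inst.hub_sites[j],
                        "quantity_supplied_tons": round(qty, 3),
                        "supplied_pct": round(100.0 * solution.y[c, k, j], 2),
                    }
                )
    supply = pd.DataFrame(rows)

    rows = []
    flows_out = solution.flows_out
    for j in open_j:
        for i, area in enumerate(inst.demand_areas):
            qty = flows_out[c, j, i]
            if qty > 1e-9:
                rows.append(
                    {
                        "food_hub_location": inst.hub_sites[j],
                        "service_area": area,
                        "demand_tons": round(inst.demand[c, i], 3),
                        "fulfilled_tons": round(qty, 3),
                        "fulfilled_pct": round(100.0 * solution.w[c, j, i], 2),
                    }
                )
    fulfillment = pd.DataFrame(rows)
    return {"hubs": hubs, "supply": supply, "fulfillment": fulfillment}
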