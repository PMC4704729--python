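"""Single-locus coalescent simulation with non-contemporaneous sampling.

Two routes through the same stochastic process:

* :func:`simulate_genealogy` — a readable pure-Python implementation that
  returns an explicit :class:`Genealogy` (topology + node times).  Use it for
  small numbers of trees, for inspecting genealogies, and with
  :func:`drop_mutation` for per-tree mutation placement.
* :func:`simulate_sites` / :func:`simulate_projection` — a compiled bulk path
  that simulates hundreds of thousands of independent sites per second,
  emitting only what projection analysis needs: the panel derived-allele
  count and the test lineage's allele at each site.

Mutation model: infinite sites.  Each polymorphic site carries exactly one
mutation, placed on a branch with probability proportional to branch length,
and a genealogy contributes sites in proportion to its total branch length
(the bulk path draws a Poisson number of sites per tree at a rate calibrated
to average one, so site counts are exact and sites are independent).  The
absolute mutation rate never needs to be specified: the projection
conditions on the panel frequency, so only relative branch lengths matter.
:func:`drop_mutation` places a mutation on one *given* tree — exact
conditionally on that tree; ensembles of sites must also weight trees by
length, which :func:`simulate_sites` does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _engine
from .demography import (
    DemographicModel,
    ModelValidationError,
    PopulationSplit,
    PulseAdmixture,
)
from .projection import ProjectionCurve

__all__ = [
    "Genealogy",
    "simulate_genealogy",
    "drop_mutation",
    "simulate_sites",
    "simulate_site_arrays",
    "simulate_projection",
]


# ----------------------------------------------------------------------
# model flattening (shared by both simulation routes)
# ----------------------------------------------------------------------
def _flatten_model(model: DemographicModel):
    model.validate()
    n_demes = len(model.demes)
    idx = {d.name: i for i, d in enumerate(model.demes)}

    ep_start, ep_N, ep_off = [], [], [0]
    for d in model.demes:
        for t, n in d.size_epochs:
            ep_start.append(t)
            ep_N.append(n)
        ep_off.append(len(ep_start))

    # pulses before splits at equal times; ties by declaration order
    keyed = []
    for order, ev in enumerate(model.events):
        if isinstance(ev, PulseAdmixture):
            # backward time: recipient's lineages move to the source
            keyed.append((ev.time, _engine.PULSE, order,
                          idx[ev.recipient], idx[ev.source], ev.fraction))
        else:
            keyed.append((ev.time, _engine.SPLIT, order,
                          idx[ev.derived], idx[ev.ancestral], 1.0))
    keyed.sort(key=lambda r: (r[0], r[1], r[2]))

    samples = sorted(enumerate(model.samples), key=lambda p: (p[1].time, p[0]))

    flat = dict(
        n_demes=n_demes,
        ep_start=np.asarray(ep_start, dtype=np.float64),
        ep_N=np.asarray(ep_N, dtype=np.float64),
        ep_off=np.asarray(ep_off, dtype=np.int64),
        ev_time=np.asarray([r[0] for r in keyed], dtype=np.float64),
        ev_kind=np.asarray([r[1] for r in keyed], dtype=np.int64),
        ev_a=np.asarray([r[3] for r in keyed], dtype=np.int64),
        ev_b=np.asarray([r[4] for r in keyed], dtype=np.int64),
        ev_frac=np.asarray([r[5] for r in keyed], dtype=np.float64),
        smp_time=np.asarray([s.time for _, s in samples], dtype=np.float64),
        smp_deme=np.asarray([idx[s.deme] for _, s in samples], dtype=np.int64),
        smp_count=np.asarray([s.lineages for _, s in samples], dtype=np.int64),
        smp_istest=np.asarray(
            [1 if s.role == "test" else 0 for _, s in samples], dtype=np.int64
        ),
    )
    bp = np.unique(
        np.concatenate([flat["ep_start"], flat["ev_time"], flat["smp_time"]])
    )
    flat["bp_times"] = bp[bp > 0.0].astype(np.float64)
    return flat


# ----------------------------------------------------------------------
# explicit genealogies (reference implementation)
# ----------------------------------------------------------------------
@dataclass
class Genealogy:
    """A coalescent tree: leaves ``0..n_leaves-1`` first, then internal nodes
    in coalescence order; the root is the last node.

    ``leaf_role`` is 1 for the test lineage, 0 for panel lineages.
    """

    node_time: np.ndarray
    parent: np.ndarray
    n_leaves: int
    leaf_role: np.ndarray
    leaf_deme: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_time.shape[0]

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    def children(self):
        kids = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            kids[self.parent[v]].append(v)
        return kids

    def leaves_below(self, node: int) -> np.ndarray:
        """Boolean mask over leaves subtended by ``node``."""
        kids = self.children()
        mask = np.zeros(self.n_leaves, dtype=bool)
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                mask[v] = True
            else:
                stack.extend(kids[v])
        return mask

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (root entry is 0)."""
        out = np.zeros(self.n_nodes)
        v = np.arange(self.n_nodes - 1)
        out[v] = self.node_time[self.parent[v]] - self.node_time[v]
        return out


def simulate_genealogy(model: DemographicModel, rng: np.random.Generator) -> Genealogy:
    """Draw one genealogy of all sampled lineages under ``model``.

    Continuous-time coalescent: within a deme of current diploid size N and k
    active lineages, the waiting time to the next coalescence is exponential
    with rate k(k-1)/(4N); lineages sampled at time t are inactive before t.
    """
    f = _flatten_model(model)
    total = int(f["smp_count"].sum())
    if total < 2:
        raise ModelValidationError("need at least two sampled lineages")

    n_nodes = 2 * total - 1
    node_time = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    leaf_role = np.zeros(total, dtype=np.int64)
    leaf_deme = np.zeros(total, dtype=np.int64)

    # assign leaf ids group by group in entry order
    leaf_ids = []
    lid = 0
    for g in range(f["smp_time"].shape[0]):
        ids = list(range(lid, lid + f["smp_count"][g]))
        lid += f["smp_count"][g]
        leaf_ids.append(ids)
        for i in ids:
            node_time[i] = f["smp_time"][g]
            leaf_role[i] = f["smp_istest"][g]
            leaf_deme[i] = f["smp_deme"][g]
    next_node = total

    members = [[] for _ in range(f["n_demes"])]
    t = 0.0
    smp_i = ev_i = bp_i = 0
    entered = 0
    n_active = 0
    n_smp = f["smp_time"].shape[0]
    n_ev = f["ev_time"].shape[0]
    bp_times = f["bp_times"]

    def deme_size(d, tt):
        n = f["ep_N"][f["ep_off"][d]]
        for j in range(f["ep_off"][d], f["ep_off"][d + 1]):
            if f["ep_start"][j] <= tt:
                n = f["ep_N"][j]
            else:
                break
        return n

    while True:
        while smp_i < n_smp and f["smp_time"][smp_i] <= t:
            d = f["smp_deme"][smp_i]
            members[d].extend(leaf_ids[smp_i])
            n_active += f["smp_count"][smp_i]
            entered += f["smp_count"][smp_i]
            smp_i += 1
        while ev_i < n_ev and f["ev_time"][ev_i] <= t:
            a, b = f["ev_a"][ev_i], f["ev_b"][ev_i]
            if f["ev_kind"][ev_i] == _engine.PULSE:
                frac = f["ev_frac"][ev_i]
                stay, move = [], []
                for v in members[a]:
                    (move if rng.random() < frac else stay).append(v)
                members[a] = stay
                members[b].extend(move)
            else:
                members[b].extend(members[a])
                members[a] = []
            ev_i += 1

        if n_active <= 1 and entered == total:
            break

        while bp_i < bp_times.shape[0] and bp_times[bp_i] <= t:
            bp_i += 1
        nb = bp_times[bp_i] if bp_i < bp_times.shape[0] else np.inf

        best_t, best_d = np.inf, -1
        for d in range(f["n_demes"]):
            k = len(members[d])
            if k >= 2:
                rate = k * (k - 1) / (4.0 * deme_size(d, t))
                w = rng.exponential(1.0 / rate)
                if t + w < best_t:
                    best_t, best_d = t + w, d
        if best_t < nb:
            d = best_d
            i1, i2 = rng.choice(len(members[d]), size=2, replace=False)
            v1, v2 = members[d][i1], members[d][i2]
            for i in sorted((i1, i2), reverse=True):
                members[d].pop(i)
            node_time[next_node] = best_t
            parent[v1] = parent[v2] = next_node
            members[d].append(next_node)
            next_node += 1
            n_active -= 1
            t = best_t
        else:
            if nb == np.inf:
                raise ModelValidationError("stranded lineages: no coalescence possible")
            t = nb

    return Genealogy(node_time, parent, total, leaf_role, leaf_deme)


def drop_mutation(tree: Genealogy, rng: np.random.Generator) -> np.ndarray:
    """Place one mutation on a branch chosen proportionally to its length.

    Returns the boolean derived mask over leaves (leaves below the mutated
    branch carry the derived allele).
    """
    if tree.n_leaves < 2:
        raise ValueError("need a tree with at least two leaves")
    lens = tree.branch_lengths()
    total = lens.sum()
    u = rng.random() * total
    node = int(np.searchsorted(np.cumsum(lens), u))
    return tree.leaves_below(node)


# ----------------------------------------------------------------------
# bulk site simulation (compiled path)
# ----------------------------------------------------------------------
def _run_kernel(flat, num, seed, mode, site_rate, derived, test, acc):
    return _engine._simulate_kernel(
        flat["n_demes"], flat["ep_start"], flat["ep_N"], flat["ep_off"],
        flat["ev_time"], flat["ev_kind"], flat["ev_a"], flat["ev_b"], flat["ev_frac"],
        flat["smp_time"], flat["smp_deme"], flat["smp_count"], flat["smp_istest"],
        flat["bp_times"], num, int(seed) % (2**32), mode, site_rate,
        derived, test, acc,
    )


def simulate_site_arrays(
    model: DemographicModel, num_sites: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``num_sites`` independent polymorphic sites.

    Returns the arrays ``(panel_derived_count, test_is_derived)``.  A short
    pilot run calibrates the per-tree site rate so that genealogies
    contribute sites in proportion to their total branch length, as the
    infinite-sites model requires.
    """
    if num_sites <= 0:
        raise ValueError("num_sites must be positive")
    f = _flatten_model(model)
    n_panel = int(f["smp_count"][f["smp_istest"] == 0].sum())
    pilot_seed, main_seed = (
        int(s.generate_state(1)[0]) for s in np.random.SeedSequence(int(seed) % (2**31)).spawn(2)
    )

    pilot_trees = 500
    acc = np.zeros((n_panel + 1, 2))
    dummy = np.empty(1, dtype=np.int64)
    status = _run_kernel(f, pilot_trees, pilot_seed, _engine.MODE_EXPECTED, 0.0,
                         dummy, dummy, acc)
    if status < 0:
        raise ModelValidationError("stranded lineages during simulation")
    site_rate = pilot_trees / acc.sum()  # one expected site per average tree

    derived = np.empty(num_sites, dtype=np.int64)
    test = np.empty(num_sites, dtype=np.int64)
    acc2 = np.zeros((n_panel + 1, 2))
    status = _run_kernel(f, num_sites, main_seed, _engine.MODE_SAMPLED, site_rate,
                         derived, test, acc2)
    if status < 0:
        raise ModelValidationError("stranded lineages during simulation")
    return derived, test


def expected_site_spectrum(
    model: DemographicModel, num_trees: int, seed: int
) -> np.ndarray:
    """Expected joint site spectrum, integrating out mutation placement.

    Simulates ``num_trees`` genealogies and accumulates every branch's raw
    length into ``spectrum[panel_count, test_flag]``; each cell is then
    proportional to the probability that a polymorphic site falls in that
    class.  This is a lower-variance estimate of the distribution
    :func:`simulate_site_arrays` samples from.
    """
    if num_trees <= 0:
        raise ValueError("num_trees must be positive")
    f = _flatten_model(model)
    n_panel = int(f["smp_count"][f["smp_istest"] == 0].sum())
    acc = np.zeros((n_panel + 1, 2))
    dummy = np.empty(1, dtype=np.int64)
    status = _run_kernel(f, num_trees, seed, _engine.MODE_EXPECTED, 0.0,
                         dummy, dummy, acc)
    if status < 0:
        raise ModelValidationError("stranded lineages during simulation")
    return acc


def simulate_sites(model: DemographicModel, num_sites: int, seed: int) -> pd.DataFrame:
    """Simulate sites and return a tidy table.

    Columns: ``site_index``, ``derived_count`` (panel), ``panel_size``,
    ``test_allele`` ("derived"/"ancestral"), ``panel_polymorphic``.  Sites
    monomorphic in the panel (count 0 or n) are retained but flagged; the
    projection excludes them downstream.
    """
    derived, test = simulate_site_arrays(model, num_sites, seed)
    n = model.bind().panel_size if not model.is_bound else model.panel_size
    return pd.DataFrame(
        {
            "site_index": np.arange(num_sites),
            "derived_count": derived,
            "panel_size": n,
            "test_allele": np.where(test == 1, "derived", "ancestral"),
            "panel_polymorphic": (derived > 0) & (derived < n),
        }
    )


def simulate_projection(
    model: DemographicModel, num_sites: int, seed: int, expected: bool = False
) -> ProjectionCurve:
    """Simulate sites under ``model`` and tally them into a projection curve.

    With ``expected=True`` the per-site mutation draw is replaced by its
    expectation over branch placement (``num_sites`` then counts genealogies);
    category weights become fractional but every downstream statistic is
    unchanged in expectation, at a fraction of the Monte Carlo noise.
    """
    bound = model if model.is_bound else model.bind()
    if bound.test_group is None:
        raise ModelValidationError("model has no test sample group")
    n = bound.panel_size
    if expected:
        acc = expected_site_spectrum(bound, num_sites, seed)
        # scale branch-length units to expected sites (one per average tree)
        acc = acc * (num_sites / acc.sum())
        sites = acc[1:n, 0] + acc[1:n, 1]
        der = acc[1:n, 1]
        return ProjectionCurve.from_category_weights(n, sites, der)
    derived, test = simulate_site_arrays(bound, num_sites, seed)
    return ProjectionCurve.from_site_counts(derived, test, n)
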