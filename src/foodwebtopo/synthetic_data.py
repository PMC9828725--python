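"""Synthetic food webs and disturbance tables with known structure.

Two generator families bracket the topologies of interest: Bernoulli-link
webs (homogeneous, binomial degree distribution — the "random" corner) and
configuration-model webs with a truncated power-law degree sequence (the
"scale-free" corner).  Trophic direction is assigned by a random total
ordering of species — the lower species of an edge is the resource — which
guarantees an acyclic web with basal species, so extinction cascades are
always exercisable.  Disturbance covariates are generated with a stated
linear dependence on the distance-to-pure-random (D2PG) plus Gaussian
noise, clipped to [0, 1].
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .web_model import FoodWeb


def _labels(S: int) -> list:
    width = len(str(S - 1))
    return [f"sp{j:0{width}d}" for j in range(S)]


def generate_random_web(
    S: int,
    connectance: float,
    seed: int,
    *,
    basal_fraction: float = 0.0,
    ecosystem: str = "unknown",
) -> FoodWeb:
    """Bernoulli-link directed web: each ordered non-self pair carries a
    link independently with probability `connectance`.

    A configured fraction of species is forced basal (no resources) by
    suppressing their incoming links; with the default 0.0 the expected
    directed link count is exactly C*S*(S-1).
    """
    if not 0.0 < connectance < 1.0:
        raise ValueError("connectance must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = _labels(S)
    mask = rng.random((S, S)) < connectance
    np.fill_diagonal(mask, False)
    if basal_fraction > 0.0:
        n_basal = max(1, int(round(basal_fraction * S)))
        basal_idx = rng.choice(S, size=n_basal, replace=False)
        mask[:, basal_idx] = False  # basal species consume nothing
    rows, cols = np.nonzero(mask)
    links = {(labels[r], labels[c]) for r, c in zip(rows, cols)}
    web = FoodWeb(
        id=f"rand_S{S}_C{connectance}_s{seed}",
        species=labels,
        links=links,
        ecosystem=ecosystem,
        location=(0.0, 0.0),
    )
    return web


def generate_scalefree_web(
    S: int,
    gamma: float,
    seed: int,
    *,
    max_retries: int = 50,
    ecosystem: str = "unknown",
) -> FoodWeb:
    """Configuration-model web with degree sequence ~ k^(-gamma), k = 1..S-1.

    Self-loops and multi-edges from the pairing are discarded.  Directions
    follow a random trophic total ordering (lower species = resource), so
    the minimal species are basal.
    """
    if gamma <= 1:
        raise ValueError("gamma must be > 1")
    if S < 10:
        raise ValueError("need S >= 10")
    rng = np.random.default_rng(seed)
    k = np.arange(1, S)
    pmf = k.astype(float) ** (-gamma)
    pmf /= pmf.sum()
    for _ in range(max_retries):
        degrees = rng.choice(k, size=S, p=pmf)
        if degrees.sum() % 2:  # configuration model needs an even sum
            degrees[rng.integers(S)] += 1
        g = nx.configuration_model(degrees.tolist(),
                                   seed=int(rng.integers(2**31)))
        g = nx.Graph(g)  # collapse multi-edges
        g.remove_edges_from(nx.selfloop_edges(g))
        if g.number_of_edges() >= 1:
            break
    else:
        raise RuntimeError("could not wire a usable degree sequence")
    labels = _labels(S)
    order = rng.permutation(S)  # trophic height per node index
    links = set()
    for u, v in g.edges():
        lo, hi = (u, v) if order[u] < order[v] else (v, u)
        links.add((labels[lo], labels[hi]))  # lower species is the resource
    return FoodWeb(
        id=f"sf_S{S}_g{gamma}_s{seed}",
        species=labels,
        links=links,
        ecosystem=ecosystem,
        location=(0.0, 0.0),
    )


def generate_disturbance_table(
    profiles: pd.DataFrame,
    beta0: float,
    beta1: float,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Disturbance = clip(beta0 + beta1 * D2PG + eps, 0, 1), eps ~ N(0, sd^2).

    Returns a copy of `profiles` with `disturbance` and `clipped` columns;
    the clipping rate is stored in ``df.attrs["clip_rate"]``.
    """
    if profiles.empty:
        raise ValueError("profiles table is empty")
    rng = np.random.default_rng(seed)
    raw = (
        beta0
        + beta1 * profiles["D2PG"].to_numpy(dtype=float)
        + rng.normal(0.0, noise_sd, size=len(profiles))
    )
    clipped = np.clip(raw, 0.0, 1.0)
    out = profiles.copy()
    out["disturbance"] = clipped
    out["clipped"] = raw != clipped
    out.attrs["clip_rate"] = float(np.mean(raw != clipped))
    return out


def fixture_webs() -> dict:
    """Deterministic analytic fixtures with known degrees and cascades.

    star_10       — 1 basal hub feeding 9 consumers; hub loss kills all.
    chain_3       — A -> B -> C; removing A extinguishes the chain.
    complete_10   — every ordered pair linked; no cascade before 50%.
    double_star_12 — 2 basal hubs, 5 exclusive consumers each.
    """
    webs = {}
    hub, consumers = "hub", [f"c{j}" for j in range(9)]
    webs["star_10"] = FoodWeb(
        "star_10", [hub] + consumers, {(hub, c) for c in consumers},
        location=(0.0, 0.0),
    )
    webs["chain_3"] = FoodWeb(
        "chain_3", ["A", "B", "C"], {("A", "B"), ("B", "C")}, location=(0.0, 0.0)
    )
    sp = [f"s{j}" for j in range(10)]
    webs["complete_10"] = FoodWeb(
        "complete_10", sp, {(a, b) for a in sp for b in sp if a != b},
        location=(0.0, 0.0),
    )
    h = ["h0", "h1"]
    cons = [f"d{j}" for j in range(10)]
    links = {(h[0], c) for c in cons[:5]} | {(h[1], c) for c in cons[5:]}
    webs["double_star_12"] = FoodWeb(
        "double_star_12", h + cons, links, location=(0.0, 0.0)
    )
    return webs


def generate_cohort(
    n_scalefree: int,
    n_random: int,
    seed: int,
    *,
    S: int = 200,
    gamma: float = 2.5,
    connectance: float = 0.15,
    basal_fraction: float = 0.0,
) -> list:
    """Mixed cohort of scale-free and Bernoulli-link webs, ecosystem-tagged
    by generator family for downstream grouping."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_scalefree + n_random) % (2**31)
    webs = []
    for j in range(n_scalefree):
        webs.append(
            generate_scalefree_web(S, gamma, int(seeds[j]), ecosystem="terrestrial")
        )
    for j in range(n_random):
        webs.append(
            generate_random_web(
                S, connectance, int(seeds[n_scalefree + j]),
                basal_fraction=basal_fraction, ecosystem="marine",
            )
        )
    return webs
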