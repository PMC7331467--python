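"""Grid-snapped, memoized probability lookup with Monte Carlo fallback.

Inside a mapper, three parameters are fixed for a whole sequencing run
(k, gamma, p, and n for skip seeds) while N and mu vary per read.  Snapping
(N, mu) to a predefined grid makes most calls pure memory lookups; entries
are computed on first use — by the transfer-matrix method, or by Monte
Carlo for MEM seeds when N exceeds ``n_switch`` — and can be persisted to
disk as JSON-lines and reloaded losslessly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .exact_seeds import SeedingOutcome, SeedingParams, off_target_exact
from .mem_seeds import DEFAULT_N_SWITCH, off_target_mem
from .skip_seeds import off_target_skip

__all__ = [
    "GridSpec",
    "ProbabilityStore",
    "snapped_lookup",
    "worst_mu_scan",
    "precompute",
]

SCHEMA_VERSION = 1
SEED_TYPES = ("exact", "skip", "mem")

#: Defaults: mu on a regular 0.01 grid over the plausible paralog range;
#: N geometrically spaced since p_off varies smoothly on that scale.
DEFAULT_MU_GRID = tuple(round(0.01 * i, 2) for i in range(21))
DEFAULT_N_GRID = (0, 1, 2, 3, 5, 7, 10, 15, 20, 30, 50, 100,
                  1_000, 10_000, 100_000, 1_000_000)


@dataclass(frozen=True)
class GridSpec:
    """Snap rule: requested (N, mu) map to the nearest grid values.

    Ties go in the conservative direction: the larger N, and the mu value
    closer to ``mu_star`` (the worst-case divergence, default the
    exact-seed worst case 0.07), both of which push p_off upward.
    """

    mu_grid: tuple[float, ...] = DEFAULT_MU_GRID
    N_grid: tuple[int, ...] = DEFAULT_N_GRID
    mu_star: float = 0.07

    def __post_init__(self) -> None:
        if not self.mu_grid or not self.N_grid:
            raise ValueError("grids must be non-empty")
        if list(self.mu_grid) != sorted(self.mu_grid) or \
                list(self.N_grid) != sorted(self.N_grid):
            raise ValueError("grids must be sorted")

    def snap(self, N: int, mu: float) -> tuple[int, float]:
        ns = np.asarray(self.N_grid)
        dn = np.abs(ns - N)
        # ties (up to float noise) toward the larger N
        n_snapped = int(ns[np.flatnonzero(dn <= dn.min() + 1e-12)[-1]])
        ms = np.asarray(self.mu_grid)
        dm = np.abs(ms - mu)
        cand = ms[np.flatnonzero(dm <= dm.min() + 1e-12)]
        mu_snapped = float(cand[np.argmin(np.abs(cand - self.mu_star))])
        return n_snapped, mu_snapped


def _compute(params: SeedingParams, seed_type: str, epsilon: float,
             n_switch: int, n_samples: int, rng_seed: int) -> SeedingOutcome:
    if seed_type == "exact":
        return off_target_exact(params, epsilon=epsilon)
    if seed_type == "skip":
        return off_target_skip(params, epsilon=epsilon)
    if seed_type == "mem":
        return off_target_mem(params, epsilon=epsilon, n_switch=n_switch,
                              n_samples=n_samples, rng_seed=rng_seed)
    raise ValueError(f"unknown seed type {seed_type!r}")


@dataclass
class ProbabilityStore:
    """In-memory map from snapped keys to outcomes, with JSONL persistence."""

    path: str | None = None
    records: dict[tuple, dict] = field(default_factory=dict)
    hits: int = 0
    computations: int = 0

    @staticmethod
    def key(seed_type: str, params: SeedingParams) -> tuple:
        return (seed_type, params.k, params.gamma, round(params.p, 12),
                params.n, params.N, round(params.mu, 12))

    def get(self, key: tuple) -> dict | None:
        rec = self.records.get(key)
        if rec is not None:
            self.hits += 1
        return rec

    def put(self, key: tuple, record: dict) -> None:
        self.records[key] = record

    def save(self, path: str | None = None) -> None:
        path = path or self.path
        if path is None:
            raise ValueError("no persistence path configured")
        with open(path, "w") as fh:
            fh.write(json.dumps({"schema_version": SCHEMA_VERSION,
                                 "kind": "seedprob-store"}) + "\n")
            for key, rec in self.records.items():
                row = {"key": list(key), **rec}
                fh.write(json.dumps(row) + "\n")

    @classmethod
    def load(cls, path: str) -> "ProbabilityStore":
        store = cls(path=path)
        with open(path) as fh:
            header = json.loads(fh.readline())
            if header.get("schema_version") != SCHEMA_VERSION:
                raise ValueError("unsupported store schema version")
            for line in fh:
                row = json.loads(line)
                key = row.pop("key")
                store.records[tuple(key[:1] + [int(key[1]), int(key[2]),
                                               float(key[3]), int(key[4]),
                                               int(key[5]), float(key[6])])] = row
        return store


def _record(outcome: SeedingOutcome) -> dict:
    return {
        "p_on": outcome.p_on, "p_off": outcome.p_off, "p_null": outcome.p_null,
        "p_no_target_seed": outcome.p_no_target_seed,
        "p_no_seed_pair": outcome.p_no_seed_pair,
        "method": outcome.method, "n_samples": outcome.n_samples,
        "stderr": outcome.stderr,
    }


def _outcome(rec: dict) -> SeedingOutcome:
    return SeedingOutcome(
        p_on=rec["p_on"], p_off=rec["p_off"], p_null=rec["p_null"],
        p_no_target_seed=rec["p_no_target_seed"],
        p_no_seed_pair=rec["p_no_seed_pair"], method=rec["method"],
        n_samples=rec.get("n_samples"), stderr=rec.get("stderr"),
    )


def snapped_lookup(params: SeedingParams, seed_type: str, grid: GridSpec,
                   store: ProbabilityStore, epsilon: float = 0.01,
                   n_switch: int = DEFAULT_N_SWITCH,
                   n_samples: int = 1_000_000,
                   rng_seed: int = 0) -> SeedingOutcome:
    """Snap (N, mu) to the grid, then return the cached or computed outcome.

    Results are a pure function of the snapped key and method, so lookups
    are independent of call order.  Store I/O failures do not prevent the
    computed value from being returned.
    """
    N, mu = grid.snap(params.N, params.mu)
    snapped = SeedingParams(k=params.k, gamma=params.gamma, p=params.p,
                            n=params.n, N=N, mu=mu)
    key = ProbabilityStore.key(seed_type, snapped)
    rec = store.get(key)
    if rec is not None:
        return _outcome(rec)
    outcome = _compute(snapped, seed_type, epsilon, n_switch, n_samples,
                       rng_seed)
    store.computations += 1
    store.put(key, _record(outcome))
    if store.path is not None:
        try:
            store.save()
        except OSError:
            pass
    return outcome


def worst_mu_scan(params: SeedingParams, seed_type: str,
                  mu_range: tuple[float, float] = (0.001, 0.2),
                  step: float = 0.001, epsilon: float = 0.01,
                  **kwargs) -> tuple[float, float]:
    """Grid-scan mu and return (mu*, p_off(mu*)), ties to the smallest mu.

    The maximizer is the worst-case divergence: below it duplicates mirror
    the target too closely to be seeded alone; above it they are rarely
    seeded at all.
    """
    if step <= 0.0:
        raise ValueError("step must be > 0")
    lo, hi = mu_range
    mus = np.arange(lo, hi + step / 2, step)
    if mus.size == 0:
        raise ValueError("empty mu range")
    best_mu, best_off = None, -1.0
    for mu in mus:
        p = SeedingParams(k=params.k, gamma=params.gamma, p=params.p,
                          n=params.n, N=params.N, mu=float(mu))
        off = _compute(p, seed_type, epsilon, kwargs.get("n_switch", DEFAULT_N_SWITCH),
                       kwargs.get("n_samples", 1_000_000),
                       kwargs.get("rng_seed", 0)).p_off
        if off > best_off + 1e-18:
            best_mu, best_off = float(mu), off
    return best_mu, best_off


def precompute(grid: GridSpec, params: SeedingParams, seed_type: str,
               out_path: str, epsilon: float = 0.01,
               n_switch: int = DEFAULT_N_SWITCH, n_samples: int = 1_000_000,
               rng_seed: int = 0) -> ProbabilityStore:
    """Fill the full (N, mu) grid offline and persist it.

    Resumes idempotently: an existing store at ``out_path`` is loaded first
    and only missing cells are computed.  Round-trips preserve doubles
    exactly (JSON repr of Python floats is lossless).
    """
    if os.path.exists(out_path):
        store = ProbabilityStore.load(out_path)
        store.path = out_path
    else:
        parent = os.path.dirname(os.path.abspath(out_path))
        if not os.path.isdir(parent):
            raise ValueError(f"unwritable path {out_path!r}")
        store = ProbabilityStore(path=out_path)
    for N in grid.N_grid:
        for mu in grid.mu_grid:
            p = SeedingParams(k=params.k, gamma=params.gamma, p=params.p,
                              n=params.n, N=int(N), mu=float(mu))
            key = ProbabilityStore.key(seed_type, p)
            if key in store.records:
                continue
            out = _compute(p, seed_type, epsilon, n_switch, n_samples, rng_seed)
            store.computations += 1
            store.put(key, _record(out))
    store.save()
    return store
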