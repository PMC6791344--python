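"""Cost and PCR-count arithmetic for the five amplicon library-prep strategies.

Method 1: standard primers, adapter ligation (Y-yoke), per-sample indexed
second-round PCR. Method 2: standard primers, then indexed fusion primers,
then a pooled second round. Method 3: indexed primers, pool, ligate, pooled
second round. Method 4: non-indexed fusion primers, per-sample second round.
Method 5: indexed fusion primers, pool, pooled second round.

Each method's cost is buy-in (indexed universal primer aliquots + locus
oligo synthesis) plus a fixed per-sample reagent cost, plus — for methods
that pool before the second PCR — a per-pool cost for the shared
limited-cycle reaction. Prices are January-2019 USD list prices shipped as a
data file; users with different vendors should edit it rather than the code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["MethodParams", "Plan", "load_method_params", "total_cost", "pcr_count", "cheapest_method"]

SAMPLES_PER_PLATE = 96


@dataclass(frozen=True)
class MethodParams:
    method: int
    itru_buy_in: float
    oligo_buy_in: float
    fixed_per_sample: float
    variable_per_pool: float | None  # None for methods with per-sample 2nd-round PCR
    pooled_itru: bool


@dataclass(frozen=True)
class Plan:
    method: int
    n_samples: int
    n_pools: int
    total_cost: float
    per_sample_cost: float
    pcr_count: int


def load_method_params(path: str | Path | None = None) -> dict[int, MethodParams]:
    """Load per-method prices (packaged defaults, or a user file of the same shape)."""
    if path is None:
        raw = json.loads(
            resources.files("taggimatrix.data").joinpath("method_costs.json").read_text()
        )
    else:
        raw = json.loads(Path(path).read_text())
    out = {}
    for key, val in raw.items():
        if key.startswith("_"):
            continue
        method = int(key)
        out[method] = MethodParams(method=method, **val)
    return out


def _params(method: int, params: dict[int, MethodParams] | None) -> MethodParams:
    table = params or load_method_params()
    if method not in table:
        raise ValueError(f"unknown method {method}; expected one of {sorted(table)}")
    return table[method]


def pcr_count(method: int, n_samples: int, n_pools: int = 1,
              params: dict[int, MethodParams] | None = None) -> int:
    """Minimum number of PCR reactions to take n_samples through a method.

    Methods 1 and 4 run two reactions per sample (2n). Method 2 runs two
    first-round reactions per sample plus one pooled second round per pool
    (2n + p). Methods 3 and 5 run one reaction per sample plus one pooled
    second round per pool (n + p). At 96 samples and one pool this gives
    192, 193, 97, 192, 97 for methods 1-5.
    """
    p = _params(method, params)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if p.pooled_itru and n_pools < 1:
        raise ValueError(f"method {method} pools before the second PCR; n_pools must be >= 1")
    if method in (1, 4):
        return 2 * n_samples
    if method == 2:
        return 2 * n_samples + n_pools
    return n_samples + n_pools  # methods 3, 5


def total_cost(method: int, n_samples: int, n_pools: int = 1,
               params: dict[int, MethodParams] | None = None) -> Plan:
    """Total and per-sample USD cost of a method at a given scale.

    total = itru_buy_in + oligo_buy_in + n_samples * fixed_per_sample
            (+ n_pools * variable_per_pool for pooled methods)
    """
    p = _params(method, params)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if p.pooled_itru and n_pools < 1:
        raise ValueError(f"method {method} requires n_pools >= 1")
    total = p.itru_buy_in + p.oligo_buy_in + n_samples * p.fixed_per_sample
    if p.pooled_itru and p.variable_per_pool is not None:
        total += n_pools * p.variable_per_pool
    return Plan(
        method=method,
        n_samples=n_samples,
        n_pools=n_pools if p.pooled_itru else 0,
        total_cost=round(total, 2),
        per_sample_cost=total / n_samples,
        pcr_count=pcr_count(method, n_samples, n_pools, params),
    )


def cheapest_method(n_samples: int, n_pools: int = 1,
                    params: dict[int, MethodParams] | None = None) -> list[Plan]:
    """Rank all five methods by total cost at the given scale (cheapest first)."""
    table = params or load_method_params()
    plans = [total_cost(m, n_samples, n_pools, table) for m in sorted(table)]
    return sorted(plans, key=lambda pl: (pl.total_cost, pl.method))
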