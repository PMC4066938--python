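"""Benchmark protocol: repeated runs, mean ± maximum deviation.

Stochastic engines (lpa, kblpa) are run ``repeats`` times with distinct
seeds derived from a master seed by a fixed counter scheme, and each metric
is reported as the mean together with the maximum absolute deviation of any
single run from that mean (the "mean ± max difference" convention).  The
deterministic engine (niblpa) is run once; its deviation is zero by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .errors import ValidationError
from .metrics import f_measure, modularity, nmi
from .partition import Partition
from .propagation import DEFAULT_MAX_ITER, run_kblpa, run_lpa, run_niblpa

log = logging.getLogger(__name__)

STOCHASTIC = {"lpa", "kblpa"}
KNOWN = {"lpa", "kblpa", "niblpa"}

_SEED_STRIDE = 1_000_003  # derived seeds: (master*stride + i) mod (2^31 - 1)


def derive_seed(master: int, index: int) -> int:
    """Per-run seed number ``index`` under master seed ``master``."""
    return (master * _SEED_STRIDE + index) % (2**31 - 1)


@dataclass(frozen=True)
class BenchConfig:
    """What to run: engines, repeat count for stochastic engines, α grid
    for niblpa, and the master seed."""

    algorithms: Sequence[str] = ("niblpa", "lpa", "kblpa")
    repeats: int = 100
    alphas: Sequence[float] = (1.0,)
    seed: int = 0
    max_iter: int = DEFAULT_MAX_ITER

    def __post_init__(self) -> None:
        unknown = set(self.algorithms) - KNOWN
        if unknown:
            raise ValidationError(f"unknown algorithm(s): {sorted(unknown)}")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")


def _summarise(values: list[float]) -> tuple[float, float]:
    mean = sum(values) / len(values)
    max_dev = max(abs(v - mean) for v in values)
    return mean, max_dev


def bench(
    G: nx.Graph,
    truth: Optional[Partition],
    config: BenchConfig,
    network: str = "network",
) -> list[dict]:
    """Run the configured engines on one graph; return tidy result rows.

    Each row carries the network name, algorithm, α (niblpa only), number
    of runs actually performed, and mean/max-deviation for NMI and pair-F
    (when ``truth`` is given) and modularity Q.
    """
    rows: list[dict] = []
    for algo in config.algorithms:
        variants = config.alphas if algo == "niblpa" else [None]
        for alpha in variants:
            if algo in STOCHASTIC:
                n_runs = config.repeats
                results = [
                    (run_lpa if algo == "lpa" else run_kblpa)(
                        G,
                        seed=derive_seed(config.seed, i),
                        max_iter=config.max_iter,
                    )
                    for i in range(n_runs)
                ]
            else:
                if config.repeats > 1:
                    log.info("niblpa is deterministic; running once, not %d times",
                             config.repeats)
                n_runs = 1
                results = [run_niblpa(G, alpha=alpha, max_iter=config.max_iter)]
            row: dict = {
                "network": network,
                "algorithm": algo,
                "alpha": "" if alpha is None else alpha,
                "runs": n_runs,
            }
            if truth is not None:
                row["nmi_mean"], row["nmi_maxdev"] = _summarise(
                    [nmi(r.partition, truth) for r in results]
                )
                row["f1_mean"], row["f1_maxdev"] = _summarise(
                    [f_measure(r.partition, truth) for r in results]
                )
            if G.number_of_edges() > 0:
                row["q_mean"], row["q_maxdev"] = _summarise(
                    [modularity(G, r.partition) for r in results]
                )
            row["converged_all"] = all(r.converged for r in results)
            rows.append(row)
    return rows


def rows_to_tsv(rows: list[dict]) -> str:
    """Serialise bench rows to a TSV string (stable column order)."""
    if not rows:
        return ""
    columns = list(rows[0].keys())
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append(
            "\t".join(
                f"{row[c]:.6f}" if isinstance(row[c], float) else str(row[c])
                for c in columns
            )
        )
    return "\n".join(lines) + "\n"
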