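"""Run configuration shared by the factorization core and the scheduler."""

from __future__ import annotations

from dataclasses import dataclass

STRATEGIES = ("serial", "kfactor", "input-matrix")


@dataclass
class RunConfig:
    """All user-facing parameters of a consensus clustering job.

    Parameters
    ----------
    k_min, k_max
        Inclusive range of candidate ranks (number of metagenes).
    num_clusterings
        Number of NMF restarts with varied initial conditions per k.
    max_iterations
        Hard cap on multiplicative-update iterations per run.
    stop_convergence
        Number of consecutive "no change" connectivity checks required
        to declare convergence.
    stop_frequency
        Number of iterations between connectivity/divergence checks.
    max_error_difference
        Maximum absolute change in KL divergence between consecutive
        checks below which the run stops.
    strategy
        Execution strategy: "serial" (one worker), "kfactor" (all
        restarts for one k on a single worker) or "input-matrix"
        (the data matrix is block-partitioned across workers that
        jointly compute every run).
    n_workers
        Worker count for the parallel strategies; forced to 1 under
        "serial".
    base_seed
        Base of the per-run seed derivation
        ``seed = base_seed + 10000 * k + run_index``, which makes every
        (k, run) reproducible independently of execution order.
    """

    k_min: int = 2
    k_max: int = 5
    num_clusterings: int = 20
    max_iterations: int = 2000
    stop_convergence: int = 40
    stop_frequency: int = 10
    max_error_difference: float = 1e-8
    strategy: str = "serial"
    n_workers: int = 1
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError(f"k_min must be >= 1, got {self.k_min}")
        if self.k_max < self.k_min:
            raise ValueError(
                f"k_max ({self.k_max}) must be >= k_min ({self.k_min})"
            )
        if self.num_clusterings < 1:
            raise ValueError("num_clusterings must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.stop_convergence < 1:
            raise ValueError("stop_convergence must be >= 1")
        if self.stop_frequency < 1:
            raise ValueError("stop_frequency must be >= 1")
        if self.max_error_difference < 0:
            raise ValueError("max_error_difference must be >= 0")
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}"
            )
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.strategy == "serial":
            self.n_workers = 1

    @property
    def ks(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def run_seed(self, k: int, run_index: int) -> int:
        """Seed for restart ``run_index`` at rank ``k``."""
        return self.base_seed + 10000 * k + run_index
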