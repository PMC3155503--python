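"""Parameter-ensemble experiment, cluster classification and sweeps.

The central experiment asks how robust transposon control is to the
host's kinetic make-up: every rate constant is drawn at random from a
100-fold range around its reference value, the invasion of a single
active TE is simulated to the two-year horizon, and each run is placed
into one of three outcome clusters:

``red``
    "no invasion": the element never expanded (terminal
    ``T_act + T_sil <= 2``).
``green``
    "controlled": the element invaded but the host keeps cytoplasmic
    VLP levels low.
``blue``
    a variant-specific third regime — in the RdRP model an
    "out of control" cluster with an excess of silenced copies yet
    persistently high VLP (weak primed amplification); in the antisense
    model a "low VLP" cluster where massive silencing floods the
    cytoplasm with antisense RNA.

Runs whose state exceeds the overflow guard before the horizon
(uncontrolled invasions blow up in finite time) are kept and labelled
``unclassified``; fractions are always reported relative to the full
ensemble size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import ModelVariant, ReactionNetwork, build_network
from .ode import (
    HORIZON_HOURS,
    OVERFLOW_LIMIT,
    IntegrationError,
    TerminalOutcome,
    integrate_ode,
    terminal_outcome,
)
from .params import ParameterSet, default_parameters

__all__ = [
    "ClusterRules",
    "EnsembleConfig",
    "RunOutcome",
    "sample_parameter_set",
    "run_ensemble",
    "classify_outcome",
    "classify_kmeans",
    "summarize_clusters",
    "outcomes_to_frame",
    "histogram2d_log",
    "sweep_axes",
    "sweep_2d",
]

CLUSTERS = ("red", "green", "blue", "unclassified")

#: Parameters treated as integers when sampled.
_INTEGER_PARAMS = frozenset({"n"})
#: Default randomized set: every kinetic constant.  The siRNA burst size
#: ``n`` is a structural count of the dicing reaction, not a rate, and is
#: held at its reference value unless explicitly listed.
DEFAULT_SAMPLED: tuple[str, ...] = tuple(
    name for name in ParameterSet.names() if name != "n"
)
#: Parameters clamped to [0, 1] (probabilities/fractions).
_FRACTION_PARAMS = frozenset({"f"})


@dataclass(frozen=True)
class ClusterRules:
    """Thresholds of the rule-based cluster classifier.

    ``red`` is defined unambiguously by the total-TE threshold.  The
    green/blue boundary is model specific: in the RdRP model the blue
    (out of control) cluster is recognised by its excess of silenced
    over active copies (ratio >= ``r_blue``); in the antisense model the
    blue (low VLP) cluster combines heavy silencing (``T_sil >=
    s_high``) with a suppressed cytoplasm (``VLP <= v_low``).  The
    hairpin model has no third cluster.
    """

    total_te_red: float = 2.0
    r_blue: float = 200.0
    v_low: float = 0.5
    s_high: float = 1e3


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of one randomized-parameter ensemble."""

    variant: ModelVariant | str = ModelVariant.RDRP
    n_runs: int = 10_000
    fold_range: float = 100.0
    horizon: float = HORIZON_HOURS
    seed: int = 0
    reference: ParameterSet = field(default_factory=default_parameters)
    sampled: tuple[str, ...] = DEFAULT_SAMPLED
    sampler: str = "linear"  # "linear" (uniform) or "log" (log-uniform)
    risc_law: str = "mass_action"
    rules: ClusterRules = field(default_factory=ClusterRules)
    rtol: float = 1e-6
    atol: float = 1e-9
    overflow: float = OVERFLOW_LIMIT

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", ModelVariant.coerce(self.variant))
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not self.fold_range > 1:
            raise ValueError("fold_range must be > 1")


@dataclass(frozen=True)
class RunOutcome:
    """Terminal state, sampled parameters and cluster label of one run."""

    run_id: int
    variant: ModelVariant
    params: ParameterSet
    T_act: float
    T_sil: float
    VLP: float
    control: bool
    diverged: bool
    failed: bool = False
    cluster: str = "unclassified"

    @property
    def total_te(self) -> float:
        return self.T_act + self.T_sil


def sample_parameter_set(
    reference: ParameterSet,
    fold_range: float,
    rng: np.random.Generator,
    sampled: Iterable[str] | None = None,
    sampler: str = "linear",
) -> ParameterSet:
    """Draw one parameter set around ``reference``.

    Each sampled rate is drawn from
    ``[ref / sqrt(fold_range), ref * sqrt(fold_range)]`` — for a
    100-fold range, ``[ref/10, 10*ref]`` — uniformly (default) or
    log-uniformly (``sampler="log"``).  The success fraction ``f`` is
    clamped to [0, 1] and the siRNA burst size ``n``, if sampled, is
    rounded to an integer >= 1.
    """
    half = np.sqrt(fold_range)
    if sampled is None:
        sampled = DEFAULT_SAMPLED
    updates: dict[str, float] = {}
    for name in sampled:
        ref = reference[name]
        if ref == 0.0:
            continue
        if sampler == "log":
            value = ref * fold_range ** (rng.random() - 0.5)
        elif sampler == "linear":
            value = rng.uniform(ref / half, ref * half)
        else:
            raise ValueError(f"sampler must be 'log' or 'linear', got {sampler!r}")
        if name in _FRACTION_PARAMS:
            value = min(max(value, 0.0), 1.0)
        if name in _INTEGER_PARAMS:
            value = max(1.0, round(value))
        updates[name] = value
    return reference.with_updates(**updates)


def _run_rng(master_seed: int, run_id: int) -> np.random.Generator:
    # Counter-based: each run's stream depends only on (master, run_id),
    # so ensembles reproduce regardless of execution order.
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((master_seed, run_id))))


def run_ensemble(
    config: EnsembleConfig,
    network: ReactionNetwork | None = None,
) -> list[RunOutcome]:
    """Simulate ``config.n_runs`` independent invasions and classify them.

    Solver failures are recorded on the outcome (``failed=True``) and
    never abort the batch; diverged (overflowing) runs keep the state at
    the moment the guard tripped.
    """
    net = network or build_network(config.variant, risc_law=config.risc_law)
    outcomes: list[RunOutcome] = []
    for run_id in range(config.n_runs):
        rng = _run_rng(config.seed, run_id)
        params = sample_parameter_set(
            config.reference, config.fold_range, rng,
            sampled=config.sampled, sampler=config.sampler,
        )
        try:
            traj = integrate_ode(
                net, params, t_end=config.horizon, output_grid=None,
                rtol=config.rtol, atol=config.atol, overflow=config.overflow,
            )
            term = terminal_outcome(traj)
            outcome = RunOutcome(
                run_id=run_id, variant=net.variant, params=params,
                T_act=term.T_act, T_sil=term.T_sil, VLP=term.VLP,
                control=term.control, diverged=term.diverged,
            )
        except IntegrationError:
            outcome = RunOutcome(
                run_id=run_id, variant=net.variant, params=params,
                T_act=np.nan, T_sil=np.nan, VLP=np.nan,
                control=False, diverged=False, failed=True,
            )
        outcome = replace(outcome, cluster=classify_outcome(outcome, net.variant, config.rules))
        outcomes.append(outcome)
    return outcomes


def classify_outcome(
    outcome: RunOutcome | TerminalOutcome,
    variant: ModelVariant | str,
    rules: ClusterRules | None = None,
) -> str:
    """Assign the cluster label of one terminal outcome."""
    variant = ModelVariant.coerce(variant)
    rules = rules or ClusterRules()
    if getattr(outcome, "failed", False) or outcome.diverged:
        return "unclassified"
    total = outcome.T_act + outcome.T_sil
    if not np.isfinite(total):
        return "unclassified"
    if total <= rules.total_te_red:
        return "red"
    if variant is ModelVariant.RDRP:
        ratio = outcome.T_sil / max(outcome.T_act, 1e-300)
        return "blue" if ratio >= rules.r_blue else "green"
    if variant is ModelVariant.ANTISENSE:
        if outcome.VLP <= rules.v_low and outcome.T_sil >= rules.s_high:
            return "blue"
        return "green"
    return "green"  # hairpin: no third cluster


def classify_kmeans(
    outcomes: Sequence[RunOutcome],
    k: int,
    rng_seed: int = 0,
    floor: float = 1e-6,
) -> list[str]:
    """Alternative classifier: k-means on (log T_act, log T_sil, log VLP).

    ``k`` counts all clusters including the red one (3 for the RdRP and
    antisense models, 2 for hairpin).  The red label is still assigned
    by the total-TE rule; k-means partitions the remaining runs into
    ``k - 1`` groups, and when more than one group exists the one with
    the highest median VLP is labelled blue.  Unclassifiable (diverged
    or failed) runs keep the ``unclassified`` label.
    """
    from scipy.cluster.vq import kmeans2

    labels = ["unclassified"] * len(outcomes)
    rules = ClusterRules()
    idx = [
        i for i, o in enumerate(outcomes)
        if not (o.failed or o.diverged) and np.isfinite(o.total_te)
    ]
    rest = []
    for i in idx:
        if outcomes[i].total_te <= rules.total_te_red:
            labels[i] = "red"
        else:
            rest.append(i)
    if not rest:
        return labels
    pts = np.log10(np.maximum(
        [[outcomes[i].T_act, outcomes[i].T_sil, outcomes[i].VLP] for i in rest], floor
    ))
    k_rest = min(max(k - 1, 1), len(rest))
    if k_rest < 2:
        for i in rest:
            labels[i] = "green"
        return labels
    _, assign = kmeans2(pts, k_rest, minit="++", seed=rng_seed)
    median_vlp = [
        np.median(pts[assign == c, 2]) if np.any(assign == c) else -np.inf
        for c in range(k_rest)
    ]
    blue_cluster = int(np.argmax(median_vlp))
    for j, i in enumerate(rest):
        labels[i] = "blue" if assign[j] == blue_cluster else "green"
    return labels


def outcomes_to_frame(outcomes: Sequence[RunOutcome]) -> pd.DataFrame:
    """One row per run: sampled parameters, terminal state, labels."""
    rows = []
    for o in outcomes:
        row = {"run_id": o.run_id, "variant": o.variant.value}
        row.update({f"param_{k}": v for k, v in o.params.items()})
        row.update(
            T_act=o.T_act, T_sil=o.T_sil, VLP=o.VLP, total_te=o.total_te,
            control=o.control, diverged=o.diverged, failed=o.failed,
            cluster=o.cluster,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_clusters(
    outcomes: Sequence[RunOutcome],
    variant: ModelVariant | str | None = None,
) -> pd.DataFrame:
    """Per-cluster medians and fractions.

    Columns are clusters; rows are ``median_T_act``, ``median_T_sil``,
    ``median_VLP``, ``frac_runs`` (relative to the full ensemble) and
    ``frac_controlled`` (share of cluster members with VLP < 1).  Empty
    clusters report NaN medians and fraction 0.
    """
    n_total = len(outcomes)
    if n_total == 0:
        raise ValueError("no outcomes to summarize")
    if variant is not None:
        variant = ModelVariant.coerce(variant)
        outcomes = [o for o in outcomes if o.variant is variant]
    data = {}
    for cluster in CLUSTERS:
        members = [o for o in outcomes if o.cluster == cluster]
        if members:
            col = {
                "median_T_act": float(np.median([o.T_act for o in members])),
                "median_T_sil": float(np.median([o.T_sil for o in members])),
                "median_VLP": float(np.median([o.VLP for o in members])),
                "frac_runs": len(members) / n_total,
                "frac_controlled": float(np.mean([o.VLP < 1.0 for o in members])),
            }
        else:
            col = {
                "median_T_act": np.nan, "median_T_sil": np.nan,
                "median_VLP": np.nan, "frac_runs": 0.0, "frac_controlled": np.nan,
            }
        data[cluster] = col
    return pd.DataFrame(data)


def histogram2d_log(
    outcomes: Sequence[RunOutcome],
    x_field: str = "T_act",
    y_field: str = "T_sil",
    bins: int = 50,
    floor: float = 1e-6,
    range_decades: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-dimensional histogram on log10 axes (plotting substrate).

    Values below ``floor`` are clamped to it before the log transform.
    Returns (counts, x_edges, y_edges) with edges in log10 units.
    """
    xs = np.array([getattr(o, x_field) for o in outcomes], dtype=float)
    ys = np.array([getattr(o, y_field) for o in outcomes], dtype=float)
    ok = np.isfinite(xs) & np.isfinite(ys)
    lx = np.log10(np.maximum(xs[ok], floor))
    ly = np.log10(np.maximum(ys[ok], floor))
    counts, xe, ye = np.histogram2d(lx, ly, bins=bins, range=range_decades)
    return counts, xe, ye


#: Recruitment (dsRNA-formation) parameters available per variant:
#: nuclear axis first, cytoplasmic axis second.
SWEEP_PARAMS = {
    ModelVariant.RDRP: ("p_n", "p_c"),
    ModelVariant.ANTISENSE: ("p_nx", "p_cx"),
    ModelVariant.HAIRPIN: ("p_nx", "p_cxx"),
}


def sweep_axes(variant: ModelVariant | str) -> tuple[str, str]:
    """The (nuclear, cytoplasmic) recruitment parameters of a variant."""
    return SWEEP_PARAMS[ModelVariant.coerce(variant)]


def sweep_2d(
    variant: ModelVariant | str,
    param_x: str,
    param_y: str,
    grid_x: Sequence[float],
    grid_y: Sequence[float],
    base: ParameterSet | None = None,
    horizon: float = HORIZON_HOURS,
    risc_law: str = "mass_action",
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Total TE count at the horizon over a 2D recruitment-parameter grid.

    All other parameters stay at ``base`` (defaults).  Returns a tidy
    frame with columns ``param_x``-name, ``param_y``-name, ``total_te``,
    ``VLP`` and ``diverged``; diverged grid points carry the state at
    the overflow guard.
    """
    variant = ModelVariant.coerce(variant)
    valid = SWEEP_PARAMS[variant]
    for p in (param_x, param_y):
        if p not in valid:
            raise ValueError(
                f"parameter {p!r} is not a recruitment parameter of the "
                f"{variant.value} model; valid choices: {', '.join(valid)}"
            )
    base = base or default_parameters()
    net = build_network(variant, risc_law=risc_law)
    rows = []
    for x in grid_x:
        for y in grid_y:
            params = base.with_updates(**{param_x: float(x), param_y: float(y)})
            traj = integrate_ode(
                net, params, t_end=horizon, output_grid=None, rtol=rtol, atol=atol
            )
            term = terminal_outcome(traj)
            rows.append({
                param_x: float(x), param_y: float(y),
                "total_te": term.total_te, "VLP": term.VLP,
                "diverged": term.diverged,
            })
    return pd.DataFrame(rows)
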