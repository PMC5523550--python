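"""Synthetic pooled-array expression data with planted regulation structure.

The generator emulates the design of a pooled one-color microarray stress
experiment: two strains (a wild-type-like control and a transcription-factor
deletion mutant), one untreated condition plus three oxidative stressors,
and exactly one array per strain x condition — no replicate columns, which
is why downstream differential-expression calling is replicate-free.

Regulation is planted per (gene, stress) in the control strain with a
configurable overlap structure across the three stressors.  The mutant
inherits the control regulation except for a configurable fraction of
(gene, stress) pairs whose response is erased or sign-flipped — the planted
notion of transcription-factor dependence.  Every planted decision is
recorded in a :class:`TruthTable`, the recovery oracle for every downstream
pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

UNTREATED = "untreated"
DEFAULT_STRAINS = ("control", "atfa")
DEFAULT_STRESSES = ("MSB", "tBOOH", "diamide")

#: Default reference gene used by the qPCR table generator (actin, AN6542).
REFERENCE_GENE = "AN6542"


@dataclass(frozen=True)
class OverlapSpec:
    """Target sharing structure of responsive genes across the three stresses.

    Fractions are relative to the smallest per-stress responsive set, so a
    feasible assignment always exists when ``all_three + each_pair <= 1``.
    """

    all_three: float = 0.05
    each_pair: float = 0.10

    def validate(self) -> None:
        for name, value in (("all_three", self.all_three), ("each_pair", self.each_pair)):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"overlap_spec.{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Fractions are per stress; ``frac_up + frac_down`` must not exceed 1.
    ``atfa_dependence_prob`` is the probability that a control-responsive
    (gene, stress) pair loses (or, with ``reversal_prob``, reverses) its
    response in the mutant.  Intensities are log-normal: baseline
    ``2**N(baseline_log2_mean, baseline_log2_sd)`` with multiplicative
    noise ``2**N(0, noise_log2_sd)`` per cell.
    """

    n_genes: int = 5000
    strains: tuple[str, str] = DEFAULT_STRAINS
    stresses: tuple[str, ...] = DEFAULT_STRESSES
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    frac_up_per_stress: float = 0.05
    frac_down_per_stress: float = 0.05
    overlap_spec: OverlapSpec = field(default_factory=OverlapSpec)
    effect_log2fc_mean: float = 3.0
    effect_log2fc_sd: float = 0.75
    atfa_dependence_prob: float = 0.5
    reversal_prob: float = 0.1
    noise_log2_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if len(self.strains) != 2:
            raise ConfigurationError("exactly two strains (control, mutant) are required")
        for name in ("frac_up_per_stress", "frac_down_per_stress",
                     "atfa_dependence_prob", "reversal_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.frac_up_per_stress + self.frac_down_per_stress > 1.0:
            raise ConfigurationError(
                "frac_up_per_stress + frac_down_per_stress must be <= 1, got "
                f"{self.frac_up_per_stress + self.frac_down_per_stress}")
        if self.baseline_log2_sd < 0 or self.noise_log2_sd < 0:
            raise ConfigurationError("standard deviations must be nonnegative")
        self.overlap_spec.validate()

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _allocate_responsive(config: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Pick responsive gene indices per stress with the requested overlap.

    Hierarchical assignment: a core shared by all three stresses first, then
    extra genes for each pair, then stress-unique genes to fill the per-stress
    totals.  Raises :class:`ConfigurationError` naming the violated constraint
    when the overlap targets are unsatisfiable.
    """
    stresses = list(config.stresses)
    n = config.n_genes
    frac_resp = config.frac_up_per_stress + config.frac_down_per_stress
    n_resp = {s: int(round(frac_resp * n)) for s in stresses}
    if len(stresses) != 3:
        # Overlap structure is defined for the canonical three-stress design;
        # fall back to independent per-stress draws otherwise.
        return {s: rng.choice(n, size=n_resp[s], replace=False) for s in stresses}

    n_min = min(n_resp.values())
    n_core = int(round(config.overlap_spec.all_three * n_min))
    n_pair_total = int(round(config.overlap_spec.each_pair * n_min))
    n_pair_extra = n_pair_total - n_core
    if n_pair_extra < 0:
        raise ConfigurationError(
            f"overlap_spec infeasible: each_pair target ({n_pair_total}) smaller than "
            f"all_three core ({n_core})")
    pairs = [(stresses[0], stresses[1]), (stresses[0], stresses[2]), (stresses[1], stresses[2])]
    # Each stress participates in two pairs plus the core.
    committed = n_core + 2 * n_pair_extra
    for s in stresses:
        if committed > n_resp[s]:
            raise ConfigurationError(
                f"overlap_spec infeasible for stress {s!r}: core + pairwise allocation "
                f"({committed}) exceeds responsive total ({n_resp[s]})")
    n_unique = {s: n_resp[s] - committed for s in stresses}
    n_distinct = n_core + 3 * n_pair_extra + sum(n_unique.values())
    if n_distinct > n:
        raise ConfigurationError(
            f"overlap_spec infeasible: {n_distinct} distinct responsive genes required "
            f"but only {n} genes simulated")

    pool = rng.permutation(n)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor:cursor + k]
        cursor += k
        return out

    core = take(n_core)
    assigned = {s: [core] for s in stresses}
    for a, b in pairs:
        block = take(n_pair_extra)
        assigned[a].append(block)
        assigned[b].append(block)
    for s in stresses:
        assigned[s].append(take(n_unique[s]))
    return {s: np.concatenate(assigned[s]).astype(int) for s in stresses}


def generate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (expression matrix, design table, truth table).

    Returns
    -------
    matrix : DataFrame, genes x samples
        Strictly positive signal intensities; one column per strain x
        condition named ``"{strain}:{condition}"``.
    design : DataFrame
        Columns ``sample_id, strain, condition`` — one row per matrix column.
    truth : DataFrame
        One row per gene x strain x stress with columns ``gene_id, strain,
        stress, planted_call, planted_log2fc, atfa_dependent``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    control, mutant = config.strains
    stresses = list(config.stresses)

    responsive = _allocate_responsive(config, rng)

    frac_resp = config.frac_up_per_stress + config.frac_down_per_stress
    p_up = config.frac_up_per_stress / frac_resp if frac_resp > 0 else 0.0

    # Planted log2 fold changes per strain, genes x stresses.
    fc = {strain: {s: np.zeros(n) for s in stresses} for strain in config.strains}
    dependent = {s: np.zeros(n, dtype=bool) for s in stresses}
    for s in stresses:
        idx = responsive[s]
        signs = np.where(rng.random(idx.size) < p_up, 1.0, -1.0)
        magnitudes = np.abs(rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd,
                                       size=idx.size))
        effect = signs * magnitudes
        fc[control][s][idx] = effect
        mutant_effect = effect.copy()
        is_dep = rng.random(idx.size) < config.atfa_dependence_prob
        flips = rng.random(idx.size) < config.reversal_prob
        mutant_effect[is_dep & ~flips] = 0.0
        mutant_effect[is_dep & flips] *= -1.0
        fc[mutant][s][idx] = mutant_effect
        dependent[s][idx[is_dep]] = True

    baseline = np.exp2(rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n))

    columns: dict[str, np.ndarray] = {}
    design_rows = []
    for strain in config.strains:
        for condition in [UNTREATED] + stresses:
            sample_id = f"{strain}:{condition}"
            log2fc = np.zeros(n) if condition == UNTREATED else fc[strain][condition]
            noise = (np.zeros(n) if config.noise_log2_sd == 0
                     else rng.normal(0.0, config.noise_log2_sd, size=n))
            columns[sample_id] = baseline * np.exp2(log2fc + noise)
            design_rows.append({"sample_id": sample_id, "strain": strain,
                                "condition": condition})

    matrix = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    design = pd.DataFrame(design_rows)

    records = []
    for strain in config.strains:
        for s in stresses:
            effect = fc[strain][s]
            call = np.where(effect > 0, "up", np.where(effect < 0, "down", "none"))
            for i in range(n):
                records.append((gene_ids[i], strain, s, call[i], effect[i],
                                bool(dependent[s][i])))
    truth = pd.DataFrame.from_records(
        records,
        columns=["gene_id", "strain", "stress", "planted_call", "planted_log2fc",
                 "atfa_dependent"])
    return matrix, design, truth


def generate_qpcr(truth: pd.DataFrame, config: SimulationConfig, n_replicates: int = 4,
                  cp_noise_sd: float = 0.0, *, genes: list[str] | None = None,
                  reference_gene: str = REFERENCE_GENE, base_cp: float = 24.0,
                  reference_cp: float = 20.0) -> pd.DataFrame:
    """Emit a long-format qPCR crossing-point table consistent with the truth.

    One PCR cycle corresponds to a two-fold transcript change, so the CP of a
    planted gene under treatment is its untreated CP minus the planted log2
    fold change; the reference gene's expected CP is condition-independent.
    The expected downstream ΔΔCP therefore equals the planted log2fc exactly
    at ``cp_noise_sd=0``.
    """
    if n_replicates < 2:
        raise ConfigurationError(
            f"n_replicates must be >= 2 for a t-test, got {n_replicates}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if genes is None:
        genes = sorted(truth["gene_id"].unique())
    planted = truth.set_index(["gene_id", "strain", "stress"])["planted_log2fc"]

    rows = []
    for strain in config.strains:
        for condition in [UNTREATED] + list(config.stresses):
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, cp_noise_sd) if cp_noise_sd > 0 else 0.0
                rows.append((reference_gene, strain, condition, rep, reference_cp + noise))
                for g in genes:
                    if condition == UNTREATED:
                        expected = base_cp
                    else:
                        expected = base_cp - float(planted.get((g, strain, condition), 0.0))
                    noise = rng.normal(0.0, cp_noise_sd) if cp_noise_sd > 0 else 0.0
                    rows.append((g, strain, condition, rep, expected + noise))
    return pd.DataFrame(rows, columns=["gene_id", "strain", "condition", "replicate", "cp"])
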