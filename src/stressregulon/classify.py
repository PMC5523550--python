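"""Set-logic classification of stress regulons across strains.

Inputs are per-gene up/down/none calls for every strain x stress contrast
(a *regulation profile*).  The derived categories:

* **coregulated** — unidirectional response under all three stresses within
  a strain (the core oxidative stress response);
* **uniquely regulated** — responsive under exactly one of the three;
* **AtfA-dependent** — up (down) in the control strain while the mutant
  shows no regulation or regulation in the opposite direction, regardless
  of any intensity-ratio comparison between strains;
* **Venn partitions** — the seven disjoint regions of the three per-stress
  responsive sets;
* **transitions** — how each gene's control signature (its set of
  (stress, direction) responses) changes in the mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CALLS = ("up", "down", "none")


def profile_table(de: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long DE table into genes x (strain, stress) call matrix."""
    wide = de.pivot_table(index="gene_id", columns=["strain", "stress"], values="call",
                          aggfunc="first")
    if wide.isna().any().any():
        raise ValueError("regulation profile incomplete: missing strain/stress calls")
    return wide


def _calls(profiles: pd.DataFrame, strain: str, stress: str) -> pd.Series:
    return profiles[(strain, stress)]


def responsive_sets(profiles: pd.DataFrame, strain: str, direction: str | None = None
                    ) -> dict[str, set[str]]:
    """Per-stress sets of responsive genes for one strain.

    ``direction`` restricts to 'up' or 'down'; None takes both.
    """
    stresses = [s for st, s in profiles.columns if st == strain]
    out = {}
    for stress in stresses:
        calls = _calls(profiles, strain, stress)
        if direction is None:
            mask = calls != "none"
        else:
            mask = calls == direction
        out[stress] = set(calls.index[mask])
    return out


def coregulated(profiles: pd.DataFrame, strain: str) -> tuple[set[str], set[str]]:
    """Genes responding in the same direction under all three stresses."""
    stresses = [s for st, s in profiles.columns if st == strain]
    if len(stresses) != 3:
        raise ValueError(f"coregulation is defined for 3 stresses, found {len(stresses)}")
    up = set(profiles.index)
    down = set(profiles.index)
    for stress in stresses:
        calls = _calls(profiles, strain, stress)
        up &= set(calls.index[calls == "up"])
        down &= set(calls.index[calls == "down"])
    return up, down


def uniquely_regulated(profiles: pd.DataFrame, strain: str) -> dict[str, set[str]]:
    """Genes responsive (either direction) under exactly one of the three stresses."""
    stresses = [s for st, s in profiles.columns if st == strain]
    if len(stresses) != 3:
        raise ValueError(f"unique regulation is defined for 3 stresses, found {len(stresses)}")
    resp = responsive_sets(profiles, strain)
    out = {}
    for stress in stresses:
        others = [resp[s] for s in stresses if s != stress]
        out[stress] = resp[stress] - others[0] - others[1]
    return out


def atfa_dependent(profiles: pd.DataFrame, control: str = "control", mutant: str = "atfa"
                   ) -> dict[str, tuple[set[str], set[str]]]:
    """Per stress: genes whose control response is absent or reversed in the mutant.

    Returns ``{stress: (dependent_up, dependent_down)}`` where dependent_up
    genes are up in the control and none-or-down in the mutant (and the
    mirror image for dependent_down).  No intensity magnitudes are compared.
    """
    stresses = [s for st, s in profiles.columns if st == control]
    out = {}
    for stress in stresses:
        c = _calls(profiles, control, stress)
        m = _calls(profiles, mutant, stress)
        dep_up = set(c.index[(c == "up") & (m != "up")])
        dep_down = set(c.index[(c == "down") & (m != "down")])
        out[stress] = (dep_up, dep_down)
    return out


def venn_partition(sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Counts of the 7 disjoint regions of three sets.

    Keys are sorted tuples of the set labels whose intersection (exclusively)
    the region represents; values sum to the size of the union.
    """
    if len(sets) != 3:
        raise ValueError(f"venn_partition requires exactly 3 sets, got {len(sets)}")
    labels = list(sets)
    universe = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    from itertools import combinations
    for r in (1, 2, 3):
        for combo in combinations(labels, r):
            inside = set(universe)
            for lab in combo:
                inside &= sets[lab]
            for lab in labels:
                if lab not in combo:
                    inside -= sets[lab]
            regions[tuple(sorted(combo))] = len(inside)
    return regions


@dataclass
class ClassificationResult:
    """Full classification of a two-strain, three-stress regulation profile."""

    coregulated_up: dict[str, set[str]]
    coregulated_down: dict[str, set[str]]
    unique: dict[str, dict[str, set[str]]]  # strain -> stress -> genes
    atfa_dependent_up: dict[str, set[str]]  # stress -> genes
    atfa_dependent_down: dict[str, set[str]]
    venn: dict[tuple[str, str], dict[tuple[str, ...], int]]  # (strain, direction) -> regions


def classify(profiles: pd.DataFrame, control: str = "control", mutant: str = "atfa"
             ) -> ClassificationResult:
    coreg_up, coreg_down, unique, venn = {}, {}, {}, {}
    for strain in (control, mutant):
        up, down = coregulated(profiles, strain)
        coreg_up[strain], coreg_down[strain] = up, down
        unique[strain] = uniquely_regulated(profiles, strain)
        for direction in ("up", "down"):
            venn[(strain, direction)] = venn_partition(
                responsive_sets(profiles, strain, direction))
    dep = atfa_dependent(profiles, control, mutant)
    return ClassificationResult(
        coregulated_up=coreg_up,
        coregulated_down=coreg_down,
        unique=unique,
        atfa_dependent_up={s: d[0] for s, d in dep.items()},
        atfa_dependent_down={s: d[1] for s, d in dep.items()},
        venn=venn,
    )


# ---------------------------------------------------------------------------
# Transition taxonomy between the two strains
# ---------------------------------------------------------------------------

@dataclass
class TransitionRecord:
    gene_id: str
    control_signature: frozenset  # of (stress, direction)
    mutant_signature: frozenset
    category: str  # primary category, precedence applied
    gained_dependence: list[tuple[str, str]] = field(default_factory=list)
    tags: list[str] = field(default_factory=list)  # all applicable secondary tags


def signature(profiles: pd.DataFrame, strain: str, gene: str) -> frozenset:
    """The set of (stress, direction) responses of one gene in one strain."""
    out = []
    for st, stress in profiles.columns:
        if st != strain:
            continue
        call = profiles.loc[gene, (strain, stress)]
        if call != "none":
            out.append((stress, call))
    return frozenset(out)


def transition_table(profiles: pd.DataFrame, control: str = "control", mutant: str = "atfa",
                     *, strict_direction: bool = False
                     ) -> tuple[list[TransitionRecord], dict[str, int]]:
    """Categorize every gene whose signature differs between the strains.

    Primary category precedence: lost_responsiveness > gained_responsiveness
    > gained_dependence > other_shift.  ``gained_dependence(A→B)`` means the
    gene responded to stress A only in the control and responds to B (B != A)
    in the mutant; the "to" stress is direction-agnostic unless
    ``strict_direction`` (then the mutant's B response must match the
    direction the gene had under A in the control).

    Returns the records for changed genes plus primary-category counts;
    secondary tag counts (without precedence) are in each record's ``tags``.
    """
    stresses = sorted({s for st, s in profiles.columns if st == control})
    coreg_c = set.union(*coregulated(profiles, control))
    coreg_m = set.union(*coregulated(profiles, mutant))

    records = []
    counts: dict[str, int] = {}
    for gene in profiles.index:
        sig_c = signature(profiles, control, gene)
        sig_m = signature(profiles, mutant, gene)
        if sig_c == sig_m:
            continue
        tags = []
        gained_dep: list[tuple[str, str]] = []

        stresses_c = {s for s, _ in sig_c}
        if len(stresses_c) == 1:
            (only_stress,) = stresses_c
            direction_c = next(d for s, d in sig_c if s == only_stress)
            for s, d in sig_m:
                if s == only_stress:
                    continue
                if strict_direction and d != direction_c:
                    continue
                gained_dep.append((only_stress, s))
        if sig_c and not sig_m:
            category = "lost_responsiveness"
        elif sig_m and not sig_c:
            category = "gained_responsiveness"
        elif gained_dep:
            category = "gained_dependence"
        else:
            category = "other_shift"

        if sig_c and not sig_m:
            tags.append("lost_responsiveness")
        if sig_m and not sig_c:
            tags.append("gained_responsiveness")
        for a, b in gained_dep:
            tags.append(f"gained_dependence:{a}->{b}")
        if gene in coreg_c and gene not in coreg_m:
            tags.append("lost_coregulation")
        if gene in coreg_m and gene not in coreg_c:
            tags.append("gained_coregulation")
        if category == "other_shift" and not tags:
            tags.append("other_shift")

        counts[category] = counts.get(category, 0) + 1
        records.append(TransitionRecord(gene, sig_c, sig_m, category, gained_dep, tags))
    return records, counts


def tag_counts(records: list[TransitionRecord]) -> dict[str, int]:
    """Secondary-tag counts over transition records (no precedence applied)."""
    out: dict[str, int] = {}
    for rec in records:
        for tag in rec.tags:
            out[tag] = out.get(tag, 0) + 1
    return out


def count_group_calls(profiles: pd.DataFrame, gene_set: set[str], strain: str, stress: str,
                      direction: str) -> int:
    """Number of gene-set members with the requested call; unknown IDs are
    logged and ignored."""
    known = gene_set & set(profiles.index)
    unknown = gene_set - known
    if unknown:
        import logging
        logging.getLogger(__name__).warning(
            "%d gene IDs not in the profile universe ignored: %s",
            len(unknown), sorted(unknown)[:5])
    calls = _calls(profiles, strain, stress)
    return int((calls.loc[sorted(known)] == direction).sum())
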