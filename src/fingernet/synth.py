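"""Synthetic spectra and toy metabolic networks.

The generator emulates the statistical structure the downstream analysis
assumes: a multi-group exposure design (one vehicle control plus dose
groups), per-metabolite multi-bin signatures at fixed chemical shifts with
group-dependent effect sizes, i.i.d. measurement noise, a per-sample
multiplicative size factor (the reason total-area normalization exists),
and one structured rank-one confounder whose per-sample scores are drawn
independently of the treatment labels -- exactly the kind of variation
orthogonal signal correction is meant to remove.

It does not attempt free-induction-decay simulation, Lorentzian peak
shapes or J-coupling multiplets; a "signature" is simply a set of bins
whose mean is shifted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import StudyDesign, default_design
from .network import Metabolite, MetabolicNetwork, Reaction
from .preprocess import SpectraMatrix

__all__ = [
    "SignatureSpec",
    "simulate_spectra",
    "demo_signatures",
    "signatures_from_shift_table",
    "generate_toy_network",
    "demo_metabolic_network",
]

#: Baseline offset, in units of noise SD; large enough that additive noise
#: essentially never drives an intensity negative.
_BASELINE_SDS = 20.0
#: SD of the log of the per-sample multiplicative size factor.
_SIZE_FACTOR_LOG_SD = 0.05


@dataclass(frozen=True)
class SignatureSpec:
    """Where and how strongly one metabolite shows up in the spectra.

    ``effect_by_group`` gives the signed mean shift per group in units of
    the noise SD; the control group must have effect 0 (or be absent).
    ``directions`` optionally flips the sign per bin (default all +1),
    emulating signals that move opposite ways at different shifts.
    """

    metabolite: str
    bin_ppms: tuple[float, ...]
    effect_by_group: dict[str, float]
    directions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_ppms", tuple(float(p) for p in self.bin_ppms))
        dirs = self.directions or tuple(1 for _ in self.bin_ppms)
        if len(dirs) != len(self.bin_ppms):
            raise ValueError(f"{self.metabolite}: directions/bin_ppms length mismatch")
        if any(d not in (-1, 1) for d in dirs):
            raise ValueError(f"{self.metabolite}: directions must be +1/-1")
        object.__setattr__(self, "directions", tuple(dirs))


def simulate_spectra(
    design: StudyDesign,
    signatures: list[SignatureSpec],
    n_bins: int = 200,
    noise_sd: float = 1.0,
    confounder_sd: float = 2.0,
    seed: int = 0,
    ppm_range: tuple[float, float] = (0.5, 4.5),
    intensity_scale: str = "linear",
    size_factor_sd: float = _SIZE_FACTOR_LOG_SD,
) -> SpectraMatrix:
    """Generate a labeled synthetic intensity matrix.

    Each row is ``f_i * (baseline + signal_i + confounder_i + noise_i)``
    with ``f_i ~ lognormal(0, 0.05)``.  Signal bins of group g are shifted
    by ``effect_by_group[g] * noise_sd``; the confounder is a rank-one term
    ``s v^T`` with ``s ~ N(0, confounder_sd)`` drawn independently of the
    labels and ``v`` a fixed random unit loading.  With
    ``intensity_scale="lognormal"`` the same structure is built on the log
    scale and exponentiated (multiplicative signal).

    Same seed, same arguments -> bitwise-identical output.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if confounder_sd < 0:
        raise ValueError("confounder_sd must be >= 0")
    if intensity_scale not in {"linear", "lognormal"}:
        raise ValueError(f"unknown intensity_scale {intensity_scale!r}")
    distinct_bins = {p for s in signatures for p in s.bin_ppms}
    if n_bins < len(distinct_bins):
        raise ValueError("n_bins smaller than the number of distinct signature bins")

    lo, hi = min(ppm_range), max(ppm_range)
    bin_width = (hi - lo) / n_bins
    centers = hi - bin_width * (np.arange(n_bins) + 0.5)  # descending

    # map each signature ppm to the nearest bin center
    effects = np.zeros((len(design.groups), n_bins))
    group_idx = {g: j for j, g in enumerate(design.groups)}
    for sig in signatures:
        bad = [g for g in sig.effect_by_group if g not in group_idx]
        if bad:
            raise ValueError(f"{sig.metabolite}: unknown group(s) {bad}")
        ctrl_eff = sig.effect_by_group.get(design.control_group, 0.0)
        if ctrl_eff != 0.0:
            raise ValueError(f"{sig.metabolite}: control-group effect must be 0")
        for ppm, direction in zip(sig.bin_ppms, sig.directions):
            if not (lo <= ppm <= hi):
                raise ValueError(
                    f"{sig.metabolite}: shift {ppm} ppm outside the simulated "
                    f"axis [{lo}, {hi}]"
                )
            j = int(np.argmin(np.abs(centers - ppm)))
            for g, e in sig.effect_by_group.items():
                effects[group_idx[g], j] += direction * e * noise_sd

    rng = np.random.default_rng(seed)
    n = design.n_samples
    v = rng.normal(size=n_bins)
    v /= np.linalg.norm(v)
    # variates are drawn unconditionally and scaled afterwards, so runs that
    # differ only in confounder_sd/size_factor_sd share the same noise stream
    s = confounder_sd * rng.normal(size=n)
    noise = rng.normal(scale=noise_sd, size=(n, n_bins))
    size_factor = np.exp(size_factor_sd * rng.normal(size=n))

    rows_effects = effects[[group_idx[g] for g in design.labels]]
    baseline = _BASELINE_SDS * noise_sd
    core = baseline + rows_effects + np.outer(s, v) + noise
    if intensity_scale == "lognormal":
        X = np.exp(core / baseline) * size_factor[:, None]
    else:
        X = core * size_factor[:, None]
        if (X < 0).any():
            warnings.warn("clipping negative synthetic intensities at 0")
            X = np.clip(X, 0.0, None)
    return SpectraMatrix(X, centers, bin_width, tuple(design.sample_ids))


# ----------------------------------------------------------------------
def demo_signatures(
    design: StudyDesign,
    n_signal_bins: int = 10,
    effect: float = 3.0,
    seed: int = 0,
    dose_profile: str = "mixed",
) -> list[SignatureSpec]:
    """Signature set for demonstration and calibration runs.

    Groups other than the control are taken in ``group_index`` order as
    high -> low dose within each compound.  ``dose_profile``:

    - ``"mixed"`` (default): one third of the bins affected at every dose,
      one third dose-graded (1, 0.6, 0.3 of ``effect``), one third at the
      highest dose only -- the qualitative pattern of real discriminant
      tables, and the one that makes dose groups mutually separable.
    - ``"uniform"``: every exposed group gets the full ``effect`` on every
      signal bin.

    Bin positions are drawn without replacement from the default ppm axis.
    """
    rng = np.random.default_rng(seed)
    lo, hi = 0.5, 4.5
    ppms = rng.choice(
        np.round(np.linspace(lo + 0.05, hi - 0.05, 200), 3),
        size=n_signal_bins,
        replace=False,
    )
    exposed = [g for g in design.groups if g != design.control_group]
    by_compound: dict[str, list[str]] = {}
    for g in exposed:
        by_compound.setdefault(g.split("_")[0], []).append(g)

    sigs = []
    for k, ppm in enumerate(sorted(ppms)):
        eff: dict[str, float] = {}
        for doses in by_compound.values():
            grades = np.linspace(1.0, 0.3, len(doses)) if len(doses) > 1 else [1.0]
            for rank, g in enumerate(doses):
                if dose_profile == "uniform":
                    eff[g] = effect
                elif k % 3 == 0:  # affected at every dose
                    eff[g] = effect
                elif k % 3 == 1:  # dose-graded
                    eff[g] = effect * float(grades[rank])
                else:  # highest dose only
                    eff[g] = effect if rank == 0 else 0.0
        direction = 1 if rng.random() < 0.5 else -1
        sigs.append(
            SignatureSpec(f"synthetic_m{k:02d}", (float(ppm),), eff, (direction,))
        )
    return sigs


def signatures_from_shift_table(
    table,
    design: StudyDesign,
    effect: float = 3.0,
    noise_sd_units: bool = True,
    seed: int = 0,
    ppm_range: tuple[float, float] = (0.5, 4.5),
) -> list[SignatureSpec]:
    """Turn a packaged shift/flag table into generator signatures.

    Each metabolite contributes one bin per tabulated chemical shift
    inside ``ppm_range``; the flagged groups of the table receive
    ``effect``, others 0.  Effect directions are not reported by
    discriminance tables, so a random sign per metabolite is drawn.
    """
    rng = np.random.default_rng(seed)
    lo, hi = ppm_range
    sigs = []
    for row in table.rows:
        ppms = tuple(p for p, _ in row.shifts if lo <= p <= hi)
        if not ppms:
            continue
        eff = {g: (effect if flag else 0.0) for g, flag in row.flags.items()
               if g in design.groups}
        if not any(eff.values()):
            continue
        direction = 1 if rng.random() < 0.5 else -1
        sigs.append(
            SignatureSpec(row.metabolite, ppms, eff, tuple(direction for _ in ppms))
        )
    return sigs


# ----------------------------------------------------------------------
def generate_toy_network(
    n_metabolites: int,
    n_reactions: int,
    n_compartments: int = 1,
    hub_degree: int = 0,
    seed: int = 0,
) -> MetabolicNetwork:
    """Small random bipartite metabolic network, a stand-in for a
    genome-scale reconstruction in tests.

    The single-compartment core is built connected (a random spanning
    chain of reactions, then extra random conversions).  When
    ``hub_degree > 0``, metabolite ``M00`` is wired into at least
    ``hub_degree`` reactions while every other metabolite is kept below
    that degree.  With ``n_compartments > 1`` each metabolite is
    replicated per compartment and consecutive replicas are linked by
    transport reactions (reactions operate in the first compartment).
    """
    if n_metabolites < 2:
        raise ValueError("need at least 2 metabolites")
    if n_reactions < 1:
        raise ValueError("need at least 1 reaction")
    if n_compartments < 1:
        raise ValueError("need at least 1 compartment")
    if n_reactions < n_metabolites - 1:
        raise ValueError(
            f"{n_reactions} reactions cannot connect {n_metabolites} metabolites"
        )
    if hub_degree > n_reactions:
        raise ValueError("hub_degree exceeds the number of reactions")

    rng = np.random.default_rng(seed)
    mets = [f"M{i:02d}" for i in range(n_metabolites)]
    cap = max(hub_degree - 1, 2) if hub_degree > 0 else None  # degree cap for non-hubs
    degree = dict.fromkeys(mets, 0)

    def pick(cands: list[str]) -> str:
        ok = [m for m in cands if cap is None or m == mets[0] or degree[m] < cap]
        if not ok:
            raise ValueError("infeasible degree demands for the toy network")
        return ok[rng.integers(len(ok))]

    reactions: list[Reaction] = []

    def add_rxn(sub: str, prod: str) -> None:
        rid = f"R{len(reactions):02d}"
        reactions.append(
            Reaction(rid, rid, ((sub, 1.0),), ((prod, 1.0),), reversible=True)
        )
        degree[sub] += 1
        degree[prod] += 1

    connected = [mets[0]]
    for m in mets[1:]:
        add_rxn(pick(connected), m)
        connected.append(m)
    hub = mets[0]
    while hub_degree > 0 and degree[hub] < hub_degree and len(reactions) < n_reactions:
        add_rxn(hub, pick([m for m in mets if m != hub]))
    while len(reactions) < n_reactions:
        a = pick(mets)
        b = pick([m for m in mets if m != a])
        add_rxn(a, b)
    if hub_degree > 0:
        heavy = [m for m in mets if degree[m] >= hub_degree]
        if heavy != [hub]:
            raise ValueError(f"infeasible hub constraint (degree>=cap for {heavy})")

    if n_compartments == 1:
        metabolites = [Metabolite(m, m, "c0") for m in mets]
        return MetabolicNetwork(metabolites, reactions, name="toy")

    comps = [f"c{k}" for k in range(n_compartments)]
    metabolites = [
        Metabolite(f"{m}_{c}", m, c) for m in mets for c in comps
    ]
    relocated = [
        Reaction(
            r.id,
            r.name,
            tuple((f"{m}_{comps[0]}", s) for m, s in r.substrates),
            tuple((f"{m}_{comps[0]}", s) for m, s in r.products),
            r.reversible,
        )
        for r in reactions
    ]
    transports = [
        Reaction(
            f"T_{m}_{comps[k]}_{comps[k + 1]}",
            f"transport {m}",
            ((f"{m}_{comps[k]}", 1.0),),
            ((f"{m}_{comps[k + 1]}", 1.0),),
            reversible=True,
        )
        for m in mets
        for k in range(n_compartments - 1)
    ]
    return MetabolicNetwork(metabolites, relocated + transports, name="toy")


# ----------------------------------------------------------------------
# curated demonstration network
# ----------------------------------------------------------------------
# Synthetic hand-curated core-metabolism network (BiGG-style base ids):
# central carbon metabolism, amino-acid transamination, urea cycle,
# branched-chain amino-acid degradation and choline metabolism, lumped
# where a pathway would add nothing topologically.  Species ids line up
# with the packaged metabolite name mapping so fingerprints extracted
# from the packaged shift tables can be mapped onto it.
_DEMO_REACTIONS = [
    ("HEX1", False, "glc_D + atp -> g6p + adp"),
    ("GLYCL", False, "g6p -> 2 pyr"),  # glycolysis, lumped
    ("SERSYN", False, "g6p -> ser_L"),  # phosphoserine branch, lumped
    ("PDH", False, "pyr + nad -> accoa + co2 + nadh"),
    ("PC", False, "pyr + co2 + atp -> oaa + adp + pi"),
    ("LDH", True, "pyr + nadh <-> lac_L + nad"),
    ("CS", False, "oaa + accoa + h2o -> cit"),
    ("ACONT", True, "cit <-> icit"),
    ("ICDH", False, "icit + nad -> akg + co2 + nadh"),
    ("AKGDH", False, "akg + nad -> succ + co2 + nadh"),
    ("SUCD", True, "succ <-> fum"),
    ("FUM", True, "fum + h2o <-> mal_L"),
    ("MDH", True, "mal_L + nad <-> oaa + nadh"),
    ("GLYK", False, "glyc + atp -> glyc3p + adp"),
    ("G3PD", True, "glyc3p + nad <-> dhap + nadh"),
    ("TPI_L", False, "dhap -> pyr"),  # lower glycolysis, lumped
    ("ALATA", True, "pyr + glu_L <-> ala_L + akg"),
    ("ASPTA", True, "oaa + glu_L <-> asp_L + akg"),
    ("GLUDH", True, "akg + nadh <-> glu_L + nad + h2o"),
    ("GLNS", False, "glu_L + atp -> gln_L + adp + pi"),
    ("ASNS", False, "asp_L + gln_L + atp -> asn_L + glu_L + amp + pi"),
    ("P5CL", False, "glu_L + nadh -> pro_L + nad + h2o"),  # proline, lumped
    ("SHMT", True, "ser_L <-> gly + for"),  # one-carbon pool as formate
    ("DMGDH", False, "dmgly -> gly"),
    ("CREATSYN", False, "arg_L + gly -> creat + orn"),  # AGAT+GAMT, lumped
    ("OTCL", False, "orn + co2 -> citr_L"),  # carbamoyl branch, lumped
    ("ARGSS", False, "citr_L + asp_L + atp -> argsuc + amp + pi"),
    ("ARGSL", True, "argsuc <-> arg_L + fum"),
    ("ARGN", False, "arg_L + h2o -> orn + urea"),
    ("VALTA", True, "val_L + akg <-> val_ka + glu_L"),
    ("ILETA", True, "ile_L + akg <-> ile_ka + glu_L"),
    ("LEUTA", True, "leu_L + akg <-> leu_ka + glu_L"),
    ("BCKDH_I", False, "ile_ka + nad -> mbcoa + co2 + nadh"),
    ("BCKDH_L", False, "leu_ka + nad -> ivcoa + co2 + nadh"),
    ("LYSDEG", False, "lys_L + akg + nad -> glu_L + aasa + nadh"),  # saccharopine, lumped
    ("TYRTA", True, "tyr_L + akg <-> hpp + glu_L"),
    ("GSHSYN", False, "glu_L + gly + atp -> gthrd + adp + pi"),  # cysteine omitted
    ("CHLK", False, "chol + atp -> cholp + adp"),
    ("GPCHOL", False, "g3pc + h2o -> chol + glyc3p"),
    ("PEAMT", False, "etha -> chol"),  # methylation, lumped
    ("ACS", False, "ac + atp -> accoa + amp + ppi"),
    ("ADK1", True, "amp + atp <-> 2 adp"),
    ("FDH", False, "for + nad -> co2 + nadh"),
]


def _parse_side(expr: str) -> tuple[tuple[str, float], ...]:
    out = []
    for term in expr.split("+"):
        parts = term.split()
        if len(parts) == 2:
            out.append((parts[1], float(parts[0])))
        elif len(parts) == 1:
            out.append((parts[0], 1.0))
        else:
            raise ValueError(f"cannot parse reaction term {term!r}")
    return tuple(out)


def demo_metabolic_network(n_compartments: int = 2) -> MetabolicNetwork:
    """Curated synthetic core-metabolism network for demonstrations.

    With ``n_compartments > 1`` every metabolite is replicated per
    compartment, reactions run in the first compartment and transport
    reactions link consecutive replicas, so compartment merging has real
    work to do.  Deterministic.
    """
    if n_compartments < 1:
        raise ValueError("need at least 1 compartment")
    reactions = []
    met_ids: dict[str, None] = {}
    for rid, rev, eqn in _DEMO_REACTIONS:
        lhs, rhs = re.split(r"<->|->", eqn)
        subs, prods = _parse_side(lhs), _parse_side(rhs)
        for m, _ in subs + prods:
            met_ids.setdefault(m, None)
        reactions.append(Reaction(rid, rid, subs, prods, rev))
    mets = list(met_ids)
    if n_compartments == 1:
        return MetabolicNetwork(
            [Metabolite(m, m, "c") for m in mets], reactions, name="demo_core"
        )
    comps = [f"c{k}" for k in range(n_compartments)]
    metabolites = [Metabolite(f"{m}_{c}", m, c) for m in mets for c in comps]
    relocated = [
        Reaction(
            r.id,
            r.name,
            tuple((f"{m}_{comps[0]}", s) for m, s in r.substrates),
            tuple((f"{m}_{comps[0]}", s) for m, s in r.products),
            r.reversible,
        )
        for r in reactions
    ]
    transports = [
        Reaction(
            f"T_{m}_{comps[k]}_{comps[k + 1]}",
            f"transport {m}",
            ((f"{m}_{comps[k]}", 1.0),),
            ((f"{m}_{comps[k + 1]}", 1.0),),
            reversible=True,
        )
        for m in mets
        for k in range(n_compartments - 1)
    ]
    return MetabolicNetwork(metabolites, relocated + transports, name="demo_core")
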