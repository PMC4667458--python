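"""FBA knockdown screen ranking metabolic genes by TAG yield per biomass.

The screen works on a stoichiometric model whose biomass objective has been
split: storage-lipid (TAG) species are removed from the biomass reaction
(BM_TAG) and exported through a dedicated exchange reaction (EX_TAG) with the
same composition. For a candidate gene g, every reaction whose gene-protein-
reaction (GPR) rule evaluates to false without g is knocked down: its flux is
capped at |v_WT| / kd_factor in the wild-type direction, where v_WT comes from
a parsimonious wild-type flux distribution maximizing BM_TAG. Four linear
programs (wild-type and perturbed, each maximizing BM_TAG and EX_TAG) give the
dimensionless score

    rho = (TAG_pert / TAG_WT) / (BM_TAG_pert / BM_TAG_WT)

rho > 1 means the knockdown hurts biomass more than TAG export, i.e. more TAG
per unit biomass. A perturbation is viable only if it retains at least
``viability_fraction`` (10 %) of wild-type biomass flux; rho is reported only
for viable perturbations.

Linear programs are solved with scipy's HiGHS interface; a parsimonious
secondary objective (minimize total absolute flux at the optimum) makes the
wild-type distribution, and hence the knockdown bounds, deterministic.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "GprRule",
    "Reaction",
    "MetabolicModel",
    "FluxDistribution",
    "KnockdownConfig",
    "KnockdownResult",
    "load_model",
    "split_tag_from_biomass",
    "fba",
    "gene_knockdown_bounds",
    "rho",
    "screen_targets",
    "precursor_genes",
    "classify_condition_overlap",
]

_INF = 1e6  # bound treated as unbounded when exporting/printing
LP_TOL = 1e-9


class ModelError(ValueError):
    pass


class UnboundedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GprRule:
    """Boolean gene-protein-reaction rule over gene identifiers.

    Gene ids may contain dots and digits (e.g. Cre02.g082750), so the rule is
    parsed with a small recursive-descent parser: OR has the lowest precedence,
    AND binds tighter, parentheses group. An empty rule is always satisfied.
    """

    def __init__(self, text: str):
        self.text = (text or "").strip()
        self._tree = _parse_gpr(self.text) if self.text else None

    @property
    def genes(self) -> frozenset[str]:
        return _tree_genes(self._tree) if self._tree is not None else frozenset()

    def evaluate(self, knocked: set[str] | frozenset[str]) -> bool:
        """True if the reaction remains catalyzed when `knocked` genes are lost."""
        if self._tree is None:
            return True
        return _tree_eval(self._tree, knocked)

    def __repr__(self) -> str:
        return f"GprRule({self.text!r})"


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


def _parse_gpr(text: str):
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        node = parse_and()
        terms = [node]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return ("or", terms) if len(terms) > 1 else node

    def parse_and():
        node = parse_atom()
        terms = [node]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        return ("and", terms) if len(terms) > 1 else node

    def parse_atom():
        tok = peek()
        if tok is None:
            raise ModelError(f"unparseable GPR (unexpected end): {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ModelError(f"unparseable GPR (missing ')'): {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelError(f"unparseable GPR near {tok!r}: {text!r}")
        return ("gene", take())

    tree = parse_or()
    if pos != len(tokens):
        raise ModelError(f"unparseable GPR (trailing tokens): {text!r}")
    return tree


def _tree_genes(node) -> frozenset[str]:
    kind = node[0]
    if kind == "gene":
        return frozenset([node[1]])
    return frozenset().union(*(_tree_genes(c) for c in node[1]))


def _tree_eval(node, knocked) -> bool:
    kind = node[0]
    if kind == "gene":
        return node[1] not in knocked
    if kind == "and":
        return all(_tree_eval(c, knocked) for c in node[1])
    return any(_tree_eval(c, knocked) for c in node[1])


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]  # metabolite -> coefficient (negative = consumed)
    lb: float = 0.0
    ub: float = math.inf
    gpr: GprRule = field(default_factory=lambda: GprRule(""))

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str):
            self.gpr = GprRule(self.gpr)
        if self.lb > self.ub:
            raise ModelError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[str]
    reactions: list[Reaction]
    biomass_id: str | None = None  # BM_TAG once TAG has been split out
    tag_exchange_id: str | None = None  # EX_TAG

    def __post_init__(self) -> None:
        known = set(self.metabolites)
        seen = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ModelError(f"duplicate reaction id {rxn.id}")
            seen.add(rxn.id)
            unknown = set(rxn.stoich) - known
            if unknown:
                raise ModelError(f"reaction {rxn.id}: unknown metabolites {sorted(unknown)}")
        if self.biomass_id and self.tag_exchange_id and self.biomass_id == self.tag_exchange_id:
            raise ModelError("BM_TAG and EX_TAG must be distinct reactions")

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(rxn_id)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset().union(*(r.gpr.genes for r in self.reactions)) if self.reactions else frozenset()

    def stoichiometric_matrix(self) -> np.ndarray:
        met_idx = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoich.items():
                S[met_idx[met], j] = coef
        return S

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoich=dict(r.stoich), gpr=GprRule(r.gpr.text)) for r in self.reactions],
            biomass_id=self.biomass_id,
            tag_exchange_id=self.tag_exchange_id,
        )

    def require_designated(self) -> None:
        for name, rid in (("BM_TAG", self.biomass_id), ("EX_TAG", self.tag_exchange_id)):
            if rid is None:
                raise ModelError(f"model {self.id!r} has no designated {name} reaction")
            if rid not in self.reaction_ids:
                raise ModelError(f"designated {name} reaction {rid!r} is absent from the model")

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        def _b(x):
            return None if math.isinf(x) else x

        doc = {
            "id": self.id,
            "metabolites": list(self.metabolites),
            "reactions": [
                {"id": r.id, "stoich": r.stoich, "lb": _b(r.lb), "ub": _b(r.ub), "gpr": r.gpr.text}
                for r in self.reactions
            ],
            "biomass_id": self.biomass_id,
            "tag_exchange_id": self.tag_exchange_id,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _from_json(path) -> MetabolicModel:
    with open(path) as fh:
        doc = json.load(fh)
    reactions = [
        Reaction(
            id=r["id"],
            stoich={m: float(c) for m, c in r["stoich"].items()},
            lb=-math.inf if r.get("lb") is None else float(r.get("lb", 0.0)),
            ub=math.inf if r.get("ub") is None else float(r.get("ub", 0.0)),
            gpr=GprRule(r.get("gpr", "")),
        )
        for r in doc["reactions"]
    ]
    return MetabolicModel(
        id=doc.get("id", "model"),
        metabolites=list(doc["metabolites"]),
        reactions=reactions,
        biomass_id=doc.get("biomass_id"),
        tag_exchange_id=doc.get("tag_exchange_id"),
    )


def _from_sbml(path) -> MetabolicModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    metabolites = [m.id for m in cm.metabolites]
    reactions = [
        Reaction(
            id=r.id,
            stoich={m.id: float(c) for m, c in r.metabolites.items()},
            lb=float(r.lower_bound),
            ub=float(r.upper_bound),
            gpr=GprRule(r.gene_reaction_rule),
        )
        for r in cm.reactions
    ]
    return MetabolicModel(id=cm.id or "model", metabolites=metabolites, reactions=reactions)


def load_model(path, *, environment_bounds: dict[str, tuple[float, float]] | None = None) -> MetabolicModel:
    """Load a model from the JSON dialect or SBML; optionally override exchange bounds.

    ``environment_bounds`` maps reaction ids to (lb, ub) and encodes the growth
    environment (e.g. mixotrophy: acetate and light uptake open, other uptakes
    closed) as configuration rather than code.
    """
    path = str(path)
    if path.endswith(".json"):
        model = _from_json(path)
    elif path.endswith((".xml", ".sbml")):
        model = _from_sbml(path)
    else:
        raise ModelError(f"unrecognized model format: {path}")
    for rid, (lb, ub) in (environment_bounds or {}).items():
        rxn = model.reaction(rid)
        rxn.lb, rxn.ub = float(lb), float(ub)
        if rxn.lb > rxn.ub:
            raise ModelError(f"environment bounds for {rid} have lb > ub")
    return model


def split_tag_from_biomass(
    model: MetabolicModel,
    tag_species: list[str],
    *,
    biomass_id: str | None = None,
    bm_tag_id: str = "BM_TAG",
    ex_tag_id: str = "EX_TAG",
) -> MetabolicModel:
    """Strip TAG species from the biomass reaction and export them via EX_TAG.

    The new exchange consumes the stripped species with their original biomass
    coefficients, so EX_TAG flux has the same TAG composition as biomass did.
    """
    if not tag_species:
        raise ModelError("tag_species must be non-empty (EX_TAG with empty stoichiometry)")
    src_id = biomass_id or model.biomass_id
    if src_id is None:
        raise ModelError("no biomass reaction designated")
    out = model.copy()
    bm = out.reaction(src_id)
    missing = [s for s in tag_species if s not in bm.stoich or bm.stoich[s] >= 0]
    if missing:
        raise ModelError(f"TAG species not consumed by the biomass reaction: {missing}")
    ex_stoich = {}
    for sp in tag_species:
        ex_stoich[sp] = bm.stoich.pop(sp)  # keep the (negative) biomass coefficient
    bm.id = bm_tag_id
    out.reactions.append(Reaction(id=ex_tag_id, stoich=ex_stoich, lb=0.0, ub=math.inf))
    out.biomass_id = bm_tag_id
    out.tag_exchange_id = ex_tag_id
    out.__post_init__()
    return out


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


@dataclass
class FluxDistribution:
    objective_id: str
    objective_value: float | None
    fluxes: dict[str, float]
    status: str  # 'optimal' | 'infeasible'

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


def _lp_bounds(model: MetabolicModel) -> list[tuple[float | None, float | None]]:
    return [
        (None if math.isinf(r.lb) else r.lb, None if math.isinf(r.ub) else r.ub)
        for r in model.reactions
    ]


def fba(model: MetabolicModel, objective_id: str, *, parsimonious: bool = True) -> FluxDistribution:
    """Maximize the objective flux subject to S v = 0 and bounds.

    With ``parsimonious`` (default) a second LP minimizes total absolute flux
    at the optimum, so the returned distribution is unique enough to derive
    reproducible knockdown bounds from.
    """
    ids = model.reaction_ids
    if objective_id not in ids:
        raise ModelError(f"objective reaction {objective_id!r} not in model")
    S = model.stoichiometric_matrix()
    n = len(ids)
    c = np.zeros(n)
    c[ids.index(objective_id)] = -1.0  # linprog minimizes
    bounds = _lp_bounds(model)
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status == 2:
        return FluxDistribution(objective_id, None, {}, "infeasible")
    if res.status == 3:
        raise UnboundedError(f"FBA objective {objective_id!r} is unbounded")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    opt = -res.fun
    fluxes = res.x
    if parsimonious:
        # min sum |v| s.t. S v = 0, bounds, objective flux held at its optimum
        A_eq = np.hstack([np.vstack([S, -c]), np.zeros((S.shape[0] + 1, n))])
        b_eq = np.concatenate([np.zeros(S.shape[0]), [opt]])
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        A_ub = np.block(
            [[np.eye(n), -np.eye(n)], [-np.eye(n), -np.eye(n)]]
        )  # v - u <= 0, -v - u <= 0
        b_ub = np.zeros(2 * n)
        bounds2 = bounds + [(0, None)] * n
        res2 = linprog(
            c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds2, method="highs"
        )
        if res2.status == 0:
            fluxes = res2.x[:n]
        # if the restricted LP hits tolerance trouble, fall back to the FBA fluxes
    return FluxDistribution(
        objective_id, float(opt), dict(zip(ids, (float(v) for v in fluxes))), "optimal"
    )


def _fva_range(model: MetabolicModel, fixed: dict[str, float], rxn_id: str) -> tuple[float, float]:
    """Flux range of rxn_id with the fluxes in `fixed` pinned (within LP_TOL)."""
    ids = model.reaction_ids
    S = model.stoichiometric_matrix()
    bounds = _lp_bounds(model)
    for rid, val in fixed.items():
        j = ids.index(rid)
        bounds[j] = (val - 1e-9, val + 1e-9)
    out = []
    j = ids.index(rxn_id)
    for sense in (1.0, -1.0):
        c = np.zeros(len(ids))
        c[j] = sense
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
        if res.status == 3:
            out.append(math.inf * -sense)
        elif res.status == 0:
            out.append(float(res.x[j]))
        else:
            out.append(0.0)
    vmin, vmax = min(out), max(out)
    return vmin, vmax


# ---------------------------------------------------------------------------
# Knockdowns and the rho screen
# ---------------------------------------------------------------------------


@dataclass
class KnockdownConfig:
    kd_factor: float = 16.0  # knocked reactions keep at most 1/kd_factor of WT flux
    viability_fraction: float = 0.10  # perturbed biomass must retain this share of WT
    gpr_mode: str = "boolean"  # 'boolean' (isozymes rescue) or 'any-association'

    def __post_init__(self) -> None:
        if self.kd_factor <= 1:
            raise ModelError("kd_factor must be > 1")
        if not (0 < self.viability_fraction < 1):
            raise ModelError("viability_fraction must be in (0, 1)")
        if self.gpr_mode not in ("boolean", "any-association"):
            raise ModelError("gpr_mode must be 'boolean' or 'any-association'")


def affected_reactions(model: MetabolicModel, gene: str, gpr_mode: str = "boolean") -> list[str]:
    out = []
    for rxn in model.reactions:
        if not rxn.gpr.text:
            continue
        if gpr_mode == "boolean":
            if not rxn.gpr.evaluate({gene}):
                out.append(rxn.id)
        else:  # any-association: no isozyme rescue
            if gene in rxn.gpr.genes:
                out.append(rxn.id)
    return out


def gene_knockdown_bounds(
    model: MetabolicModel,
    wt_flux: FluxDistribution,
    gene: str,
    cfg: KnockdownConfig = KnockdownConfig(),
) -> MetabolicModel:
    """Cap every reaction lost with `gene` at |v_WT|/kd_factor in the WT direction."""
    hits = affected_reactions(model, gene, cfg.gpr_mode)
    if not hits:
        warnings.warn(f"gene {gene!r} is absent from every GPR; knockdown is a no-op")
        return model.copy()
    out = model.copy()
    for rid in hits:
        rxn = out.reaction(rid)
        v = wt_flux.fluxes.get(rid, 0.0)
        cap = abs(v) / cfg.kd_factor
        if v > LP_TOL:
            rxn.lb, rxn.ub = 0.0, cap
        elif v < -LP_TOL:
            rxn.lb, rxn.ub = -cap, 0.0
        else:  # 1/16 of zero is zero
            rxn.lb, rxn.ub = 0.0, 0.0
    return out


@dataclass
class KnockdownResult:
    gene: str
    affected: list[str]
    bm_wt: float
    bm_pert: float | None
    tag_wt: float
    tag_pert: float | None
    viable: bool
    rho: float | None  # defined only for viable perturbations with positive WT fluxes

    @property
    def bm_ratio(self) -> float | None:
        if self.bm_pert is None or self.bm_wt <= 0:
            return None
        return self.bm_pert / self.bm_wt

    @property
    def tag_ratio(self) -> float | None:
        if self.tag_pert is None or self.tag_wt <= 0:
            return None
        return self.tag_pert / self.tag_wt


def rho(
    model: MetabolicModel,
    gene: str,
    cfg: KnockdownConfig = KnockdownConfig(),
    *,
    wt_bm: FluxDistribution | None = None,
    wt_tag: FluxDistribution | None = None,
) -> KnockdownResult:
    """Knock down one gene and score TAG-per-biomass change.

    The wild-type solutions can be passed in to amortize them across a screen.
    A gene touching no reaction leaves the model untouched, so its ratios are
    exactly 1 by construction.
    """
    model.require_designated()
    wt_bm = wt_bm or fba(model, model.biomass_id)
    wt_tag = wt_tag or fba(model, model.tag_exchange_id)
    if wt_bm.status != "optimal" or wt_tag.status != "optimal":
        raise ModelError("wild-type model is infeasible")
    bm_wt, tag_wt = wt_bm.objective_value, wt_tag.objective_value
    hits = affected_reactions(model, gene, cfg.gpr_mode)
    if not hits:
        return KnockdownResult(gene, [], bm_wt, bm_wt, tag_wt, tag_wt, True, 1.0)

    pert = gene_knockdown_bounds(model, wt_bm, gene, cfg)
    sol_bm = fba(pert, pert.biomass_id, parsimonious=False)
    sol_tag = fba(pert, pert.tag_exchange_id, parsimonious=False)
    bm_pert = sol_bm.objective_value if sol_bm.status == "optimal" else 0.0
    tag_pert = sol_tag.objective_value if sol_tag.status == "optimal" else 0.0
    viable = bm_wt > 0 and bm_pert >= cfg.viability_fraction * bm_wt - LP_TOL
    value = None
    if viable and tag_wt > 0 and bm_wt > 0 and bm_pert > 0:
        value = (tag_pert / tag_wt) / (bm_pert / bm_wt)
    return KnockdownResult(gene, hits, bm_wt, bm_pert, tag_wt, tag_pert, viable, value)


def screen_targets(
    model: MetabolicModel,
    candidate_genes,
    cfg: KnockdownConfig = KnockdownConfig(),
) -> list[KnockdownResult]:
    """Per-gene knockdown results, sorted by rho descending (ties by gene id).

    Genes absent from every GPR score rho = 1 (no perturbation); candidates not
    in the model at all are silently absent from GPRs and behave the same, so
    callers should intersect with an id map first if they want them dropped.
    """
    model.require_designated()
    wt_bm = fba(model, model.biomass_id)
    wt_tag = fba(model, model.tag_exchange_id)
    results = [
        rho(model, g, cfg, wt_bm=wt_bm, wt_tag=wt_tag) for g in sorted(set(candidate_genes))
    ]
    results.sort(key=lambda r: (-(r.rho if r.rho is not None else -math.inf), r.gene))
    return results


def targets_to_frame(results: list[KnockdownResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "rho": r.rho,
                "bm_ratio": r.bm_ratio,
                "tag_ratio": r.tag_ratio,
                "viable": r.viable,
                "is_target": bool(r.viable and r.rho is not None and r.rho > 1),
                "affected_reactions": ",".join(r.affected),
            }
            for r in results
        ],
        columns=["gene", "rho", "bm_ratio", "tag_ratio", "viable", "is_target", "affected_reactions"],
    )


# ---------------------------------------------------------------------------
# Lipid-precursor gene search and cross-starvation overlap
# ---------------------------------------------------------------------------


def precursor_genes(model: MetabolicModel, precursor_metabolite_ids) -> frozenset[str]:
    """Genes able to support production of the given precursor metabolites.

    For each precursor a temporary demand reaction is added and maximized; flux
    variability over all reactions at that optimum identifies every reaction
    that can carry nonzero flux toward the demand, and the union of their GPR
    genes is returned.
    """
    found: set[str] = set()
    for met in precursor_metabolite_ids:
        if met not in model.metabolites:
            raise ModelError(f"metabolite {met!r} not in model")
        tmp = model.copy()
        dm_id = f"__DM_{met}"
        tmp.reactions.append(Reaction(id=dm_id, stoich={met: -1.0}, lb=0.0, ub=math.inf))
        tmp.__post_init__()
        sol = fba(tmp, dm_id, parsimonious=False)
        if sol.status != "optimal" or sol.objective_value <= 1e-9:
            warnings.warn(f"precursor {met!r} cannot be produced; no genes reported for it")
            continue
        fixed = {dm_id: sol.objective_value}
        for rxn in tmp.reactions:
            if rxn.id == dm_id or not rxn.gpr.text:
                continue
            vmin, vmax = _fva_range(tmp, fixed, rxn.id)
            if max(abs(vmin), abs(vmax)) > 1e-6:
                found |= rxn.gpr.genes
    return frozenset(found)


_OVERLAP_CLASS = {
    frozenset({"N"}): "N-only",
    frozenset({"N", "S"}): "N+S",
    frozenset({"N", "P"}): "N+P",
    frozenset({"N", "S", "P"}): "N+S+P",
}


@dataclass(frozen=True)
class ConditionOverlap:
    gene: str
    downregulated_in: frozenset[str]
    overlap_class: str


def classify_condition_overlap(targets, s_down, p_down) -> list[ConditionOverlap]:
    """Classify N-starvation targets by shared downregulation in S and P starvation."""
    s_down, p_down = set(s_down), set(p_down)
    out = []
    for gene in sorted(set(targets)):
        membership = {"N"}
        if gene in s_down:
            membership.add("S")
        if gene in p_down:
            membership.add("P")
        out.append(ConditionOverlap(gene, frozenset(membership), _OVERLAP_CLASS[frozenset(membership)]))
    return out
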