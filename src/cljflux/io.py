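"""Model serialization and published-model ingestion.

The internal document format mirrors the widespread COBRA JSON dialect
(metabolites/reactions/genes with ``lower_bound``/``upper_bound``/
``gene_reaction_rule``), with a ``schema_version`` and a ``provenance``
block added and package-specific flags kept under reaction ``notes``.
Round-trips are byte-identical: keys are emitted sorted with a fixed
indentation.

``load_published_model`` ingests externally published constraint-based
models in COBRA JSON or COBRA MAT dialects (the forms genome-scale
reconstructions are distributed in), converting them to internal types.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from .errors import FormatError
from .gpr import parse_gpr
from .model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    build_model,
    formula_from_string,
    formula_to_string,
)

__all__ = ["write_model", "read_model", "load_published_model", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"


def model_to_document(model: MetabolicModel, provenance: dict | None = None) -> dict:
    """Serializable document for a model (stable ordering)."""
    doc: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "provenance": provenance or {},
        "compartments": {"c": "cytosol", "e": "extracellular"},
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": formula_to_string(m.formula),
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {k: float(r.stoichiometry[k]) for k in sorted(r.stoichiometry)},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "gene_reaction_rule": r.gpr.to_string(),
                "subsystem": r.subsystem,
                "objective_coefficient": 1.0 if r.id == model.objective_id else 0.0,
                "notes": {
                    "is_exchange": r.is_exchange,
                    "balance_exempt": r.balance_exempt,
                },
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
    }
    return doc


def write_model(model: MetabolicModel, path: str | Path, provenance: dict | None = None) -> None:
    doc = model_to_document(model, provenance)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _require(obj: dict, key: str, pointer: str):
    if key not in obj:
        raise FormatError(f"missing required key {key!r}", pointer=pointer)
    return obj[key]


def read_model(path: str | Path) -> MetabolicModel:
    """Read an internal-format JSON document back into a model."""
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}", pointer="/") from exc
    if not isinstance(doc, dict):
        raise FormatError("document root must be an object", pointer="/")
    version = _require(doc, "schema_version", "/schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})",
            pointer="/schema_version",
        )
    mets = []
    for i, m in enumerate(_require(doc, "metabolites", "/metabolites")):
        ptr = f"/metabolites/{i}"
        formula = m.get("formula", "")
        try:
            mets.append(
                Metabolite(
                    id=_require(m, "id", ptr),
                    name=m.get("name", ""),
                    formula=formula_from_string(formula) if formula else {},
                    charge=int(m.get("charge", 0)),
                    compartment=_require(m, "compartment", ptr),
                )
            )
        except ValueError as exc:
            raise FormatError(str(exc), pointer=ptr) from exc
    rxns = []
    objective = None
    for i, r in enumerate(_require(doc, "reactions", "/reactions")):
        ptr = f"/reactions/{i}"
        notes = r.get("notes", {})
        try:
            rxns.append(
                Reaction(
                    id=_require(r, "id", ptr),
                    name=r.get("name", ""),
                    stoichiometry=dict(_require(r, "metabolites", ptr)),
                    lower_bound=float(_require(r, "lower_bound", ptr)),
                    upper_bound=float(_require(r, "upper_bound", ptr)),
                    gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                    subsystem=r.get("subsystem", ""),
                    is_exchange=bool(notes.get("is_exchange", False)),
                    balance_exempt=bool(notes.get("balance_exempt", False)),
                )
            )
        except ValueError as exc:
            raise FormatError(str(exc), pointer=ptr) from exc
        if r.get("objective_coefficient", 0.0):
            objective = r["id"]
    genes = [g["id"] for g in doc.get("genes", [])]
    return build_model(mets, rxns, genes=genes, objective_id=objective)


# -- published-model ingestion --------------------------------------------

def load_published_model(path: str | Path, dialect: str = "cobra_json") -> MetabolicModel:
    """Convert a published COBRA-dialect model file to internal types.

    Supported dialects: ``cobra_json`` and ``cobra_mat``.  Bounds, GPR
    rules and the objective are preserved.  Compartment labels other
    than ``e`` map to the cytosol (the internal format models two
    compartments); this does not affect exchange handling, which keys on
    boundary topology.  The ``sbml`` dialect is not supported by this
    build (no SBML library dependency); convert to COBRA JSON first.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "cobra_json":
        return _load_cobra_json(path)
    if dialect == "cobra_mat":
        return _load_cobra_mat(path)
    if dialect == "sbml":
        raise FormatError(
            "sbml dialect not supported in this build; convert to COBRA JSON"
        )
    raise FormatError(f"unknown dialect {dialect!r}")


def _map_compartment(label: str | None) -> str:
    return "e" if str(label or "c").lower().startswith("e") else "c"


def _load_cobra_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}", pointer="/") from exc
    mets = []
    for i, m in enumerate(doc.get("metabolites", [])):
        ptr = f"/metabolites/{i}"
        formula = m.get("formula") or ""
        try:
            parsed = formula_from_string(formula) if formula else {}
        except ValueError:
            parsed = {}  # exotic formula tokens (R groups, X): treat as lumped
        mets.append(
            Metabolite(
                id=_require(m, "id", ptr),
                name=m.get("name", ""),
                formula=parsed,
                charge=int(m.get("charge") or 0),
                compartment=_map_compartment(m.get("compartment")),
            )
        )
    rxns = []
    objective = None
    for i, r in enumerate(doc.get("reactions", [])):
        ptr = f"/reactions/{i}"
        stoich = dict(_require(r, "metabolites", ptr))
        is_exchange = r["id"].startswith("EX_") and len(stoich) == 1
        rxns.append(
            Reaction(
                id=_require(r, "id", ptr),
                name=r.get("name", ""),
                stoichiometry=stoich,
                lower_bound=float(r.get("lower_bound", -1000.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                subsystem=r.get("subsystem", "") or "",
                is_exchange=is_exchange,
            )
        )
        if r.get("objective_coefficient", 0.0) and objective is None:
            objective = r["id"]
    genes = [g["id"] for g in doc.get("genes", [])]
    # exchange metabolites may be flagged cytosolic in loose files; trust topology
    return _build_loose(mets, rxns, genes, objective)


def _load_cobra_mat(path: Path) -> MetabolicModel:
    from scipy.io import loadmat

    try:
        raw = loadmat(path, simplify_cells=True)
    except Exception as exc:  # scipy raises various on malformed files
        raise FormatError(f"cannot read MAT file: {exc}") from exc
    candidates = {k: v for k, v in raw.items() if not k.startswith("__")}
    struct = None
    for v in candidates.values():
        if isinstance(v, dict) and "S" in v and "rxns" in v:
            struct = v
            break
    if struct is None:
        raise FormatError("no COBRA model struct (with S and rxns) found in MAT file")

    S = struct["S"]
    if hasattr(S, "toarray"):
        S = S.toarray()
    S = np.asarray(S, dtype=float)
    met_ids = [str(x) for x in np.atleast_1d(struct["mets"])]
    rxn_ids = [str(x) for x in np.atleast_1d(struct["rxns"])]
    lb = np.asarray(struct["lb"], dtype=float).ravel()
    ub = np.asarray(struct["ub"], dtype=float).ravel()
    cvec = np.asarray(struct.get("c", np.zeros(len(rxn_ids))), dtype=float).ravel()
    rules = struct.get("grRules", [""] * len(rxn_ids))
    rules = [str(x) if str(x) != "nan" else "" for x in np.atleast_1d(rules)]
    formulas = struct.get("metFormulas", [""] * len(met_ids))
    formulas = [str(x) if str(x) != "nan" else "" for x in np.atleast_1d(formulas)]
    charges = struct.get("metCharges", struct.get("metCharge", np.zeros(len(met_ids))))
    charges = np.asarray(charges, dtype=float).ravel()

    mets = []
    for i, mid in enumerate(met_ids):
        comp = "e" if mid.endswith("[e]") or mid.endswith("_e") else "c"
        try:
            parsed = formula_from_string(formulas[i]) if formulas[i] else {}
        except ValueError:
            parsed = {}
        mets.append(
            Metabolite(id=mid, formula=parsed, charge=int(charges[i]) if i < len(charges) else 0,
                       compartment=comp)
        )
    rxns = []
    objective = None
    for j, rid in enumerate(rxn_ids):
        col = S[:, j]
        stoich = {met_ids[i]: float(col[i]) for i in np.nonzero(col)[0]}
        is_exchange = rid.startswith("EX_") and len(stoich) == 1
        rxns.append(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=float(lb[j]),
                     upper_bound=float(ub[j]), gpr=parse_gpr(rules[j]),
                     is_exchange=is_exchange)
        )
        if cvec[j] and objective is None:
            objective = rid
    genes = [str(x) for x in np.atleast_1d(struct.get("genes", []))]
    return _build_loose(mets, rxns, genes, objective)


def _build_loose(mets, rxns, genes, objective) -> MetabolicModel:
    """Build, tolerating exchange metabolites mislabelled as cytosolic."""
    by_id = {m.id: m for m in mets}
    fixed = []
    flagged = {
        next(iter(r.stoichiometry)) for r in rxns if r.is_exchange
    }
    for m in mets:
        if m.id in flagged and m.compartment != "e":
            fixed.append(Metabolite(id=m.id, name=m.name, formula=m.formula,
                                    charge=m.charge, compartment="e"))
        else:
            fixed.append(m)
    return build_model(fixed, rxns, genes=genes, objective_id=objective)
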