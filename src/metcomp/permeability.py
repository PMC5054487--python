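"""Membrane-permeability descriptors and breaking-point prediction.

For each pathway metabolite (given as SMILES) this module computes the
standard passive-permeability descriptors -- molecular weight, H-bond donor
and acceptor counts, topological polar surface area (Ertl fragment
contributions) and an atom-contribution logP estimate (Crippen) -- and
classifies each compound into permeability classes H / MH / ML / L under a
declared, editable ruleset. The predicted breaking point of a pathway is
the most permeable non-channeled intermediate.

Protonation states are taken exactly as given in the SMILES: no automatic
(de)protonation is performed, because fragment-additive TPSA depends on the
exact species. Substrate channeling (e.g. indole inside tryptophan
synthase) is an input flag, never inferred from structure.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .errors import ParameterDomainError

__all__ = [
    "MetaboliteRecord",
    "PermeabilityRuleset",
    "compute_descriptors",
    "classify_permeability",
    "predict_breaking_point",
    "default_ruleset",
    "read_pathway_tsv",
    "records_to_frame",
]

CLASS_RANK = {"L": 0, "ML": 1, "MH": 2, "H": 3}


@dataclass
class MetaboliteRecord:
    """A pathway metabolite with computed permeability descriptors.

    ``position`` is the 1-based index along the pathway (endpoints are the
    pathway substrate and product). ``channeled`` marks intermediates that
    are handed directly between enzyme subunits and therefore cannot act as
    a breaking point.
    """

    name: str
    smiles: str
    position: int
    channeled: bool = False
    mw: float | None = None
    hbd: int | None = None
    hba: int | None = None
    logp_primary: float | None = None
    logp_secondary: float | None = None
    tpsa: float | None = None
    perm_class_1: str | None = None
    perm_class_3: str | None = None
    boundary_flag: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PermeabilityRuleset:
    """Declared thresholds for the permeability classes.

    ``one_param`` maps class labels to upper TPSA bounds (class ladder
    H < MH < ML, anything above the last bound is L). A compound lying
    exactly on a bound is assigned to the less-permeable class and flagged.

    ``three_param`` is an ordered decision list; each rule is a mapping
    with a ``class`` label and threshold conditions among ``tpsa_gt``,
    ``tpsa_le``, ``logp_gt``, ``logp_le``, ``hbd_ge``, ``mw_gt``,
    ``mw_le``. The first matching rule wins; the final rule should be
    unconditional.
    """

    one_param: dict = field(
        default_factory=lambda: {"H": 60.0, "MH": 120.0, "ML": 200.0}
    )
    three_param: list = field(
        default_factory=lambda: [
            {"class": "ML", "tpsa_gt": 140.0},
            # zwitterion clause: amphoteric compounds (several H-bond donors
            # with positive computed logP, e.g. free amino acids) permeate
            # poorly despite moderate TPSA
            {"class": "ML", "logp_gt": 0.5, "hbd_ge": 3},
            {"class": "H", "tpsa_le": 120.0},
            {"class": "MH", "tpsa_le": 135.0},
            {"class": "ML", "tpsa_le": 200.0},
            {"class": "L"},
        ]
    )

    def __post_init__(self) -> None:
        bounds = list(self.one_param.values())
        if sorted(bounds) != bounds:
            raise ParameterDomainError("one-parameter TPSA bounds must be increasing")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"one_param": self.one_param, "three_param": self.three_param}, fh)

    @classmethod
    def from_yaml(cls, path) -> "PermeabilityRuleset":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(one_param=d["one_param"], three_param=d["three_param"])


def default_ruleset() -> PermeabilityRuleset:
    """The shipped ruleset (also available as data/default_ruleset.yaml)."""
    return PermeabilityRuleset()


def compute_descriptors(name: str, smiles: str, position: int = 0,
                        channeled: bool = False, note: str = "") -> MetaboliteRecord:
    """Compute MW, HBD/HBA counts, Ertl TPSA and Crippen logP from SMILES.

    Deterministic for a fixed structure. Raises ``ParameterDomainError``
    naming the record if the SMILES does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParameterDomainError(f"record {name!r}: SMILES {smiles!r} does not parse")
    return MetaboliteRecord(
        name=name,
        smiles=smiles,
        position=position,
        channeled=channeled,
        mw=float(Descriptors.MolWt(mol)),
        hbd=int(rdMolDescriptors.CalcNumHBD(mol)),
        hba=int(rdMolDescriptors.CalcNumHBA(mol)),
        logp_primary=float(Crippen.MolLogP(mol)),
        logp_secondary=None,
        tpsa=float(rdMolDescriptors.CalcTPSA(mol)),
        note=note,
    )


def _classify_one_param(tpsa: float, ruleset: PermeabilityRuleset):
    boundary = False
    for label, bound in ruleset.one_param.items():
        if tpsa == bound:
            boundary = True  # exactly on a threshold: go to the less-permeable class
        if tpsa < bound:
            return label, boundary
    return "L", boundary


def _rule_matches(rule: dict, rec: MetaboliteRecord) -> bool:
    checks = {
        "tpsa_gt": lambda v: rec.tpsa > v,
        "tpsa_le": lambda v: rec.tpsa <= v,
        "logp_gt": lambda v: rec.logp_primary > v,
        "logp_le": lambda v: rec.logp_primary <= v,
        "hbd_ge": lambda v: rec.hbd >= v,
        "mw_gt": lambda v: rec.mw > v,
        "mw_le": lambda v: rec.mw <= v,
    }
    return all(checks[key](val) for key, val in rule.items() if key != "class")


def classify_permeability(record: MetaboliteRecord,
                          ruleset: PermeabilityRuleset | None = None) -> tuple:
    """Assign (1-parameter, 3-parameter) permeability class labels.

    The record is updated in place and the pair of labels returned.
    """
    if record.tpsa is None or record.mw is None or record.logp_primary is None:
        raise ParameterDomainError(f"record {record.name!r}: descriptors not computed")
    ruleset = ruleset or default_ruleset()
    label1, boundary = _classify_one_param(record.tpsa, ruleset)
    label3 = "L"
    for rule in ruleset.three_param:
        if _rule_matches(rule, record):
            label3 = rule["class"]
            break
    record.perm_class_1 = label1
    record.perm_class_3 = label3
    record.boundary_flag = boundary
    return label1, label3


def predict_breaking_point(pathway, ruleset: PermeabilityRuleset | None = None,
                           use: str = "3PR", ignore_channeling: bool = False):
    """Predict the pathway breaking point: the most permeable, non-channeled
    intermediate (pathway endpoints excluded).

    The score is the permeability class rank under the chosen rule column
    (``"3PR"`` or ``"1PR"``); ties are broken by lower TPSA, then lower MW.
    Returns the winning record's ``position``, or ``None`` when every
    intermediate is channeled.
    """
    pathway = sorted(pathway, key=lambda r: r.position)
    if len(pathway) < 3:
        raise ParameterDomainError("a pathway needs at least one interior intermediate")
    ruleset = ruleset or default_ruleset()
    for rec in pathway:
        if rec.perm_class_1 is None or rec.perm_class_3 is None:
            classify_permeability(rec, ruleset)
    interior = pathway[1:-1]
    candidates = [r for r in interior if ignore_channeling or not r.channeled]
    if not candidates:
        return None
    key = (lambda r: (-CLASS_RANK[r.perm_class_3], r.tpsa, r.mw)) if use == "3PR" else (
        lambda r: (-CLASS_RANK[r.perm_class_1], r.tpsa, r.mw)
    )
    return min(candidates, key=key).position


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def read_pathway_tsv(path) -> list:
    """Read a pathway table (columns: name, smiles, position, channeled
    [, note]) and compute descriptors for every row."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "smiles", "position", "channeled"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterDomainError(f"pathway TSV is missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            compute_descriptors(
                row.name, row.smiles, int(row.position),
                channeled=bool(row.channeled),
                note=str(getattr(row, "note", "") or ""),
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Descriptor table mirroring the standard column set
    (name, MW, logP, TPSA, 1PR, 3PR) plus the remaining descriptors."""
    rows = []
    for r in records:
        rows.append(
            {
                "name": r.name, "position": r.position, "MW": r.mw,
                "logP": r.logp_primary, "TPSA": r.tpsa, "HBD": r.hbd,
                "HBA": r.hba, "1PR": r.perm_class_1, "3PR": r.perm_class_3,
                "channeled": r.channeled,
            }
        )
    return pd.DataFrame(rows)


def packaged_trp_pathway_path():
    """Path to the shipped tryptophan-pathway fixture TSV."""
    return importlib.resources.files("metcomp.data") / "trp_pathway.tsv"
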