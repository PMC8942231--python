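"""Membrane-permeability prediction for metabolites from molecular
properties.

A metabolite is classified as likely membrane-permeable by an extended
Lipinski rule over six molecular descriptors: H-bond donors (HBD ≤ 5),
H-bond acceptors (HBA ≤ 10), molecular weight (MW ≤ 500 Da), topological
polar surface area (TPSA ≤ 140 Å²), rotatable bonds (RB ≤ 10), and the
predicted octanol/water partition coefficient (−0.4 ≤ XLogP3 ≤ 5.6).  Any
missing property makes the metabolite "not likely permeable".  Because
XLogP3 is frequently absent from property databases, it is imputed first by
1-nearest-neighbour regression on (MW, TPSA, HBD, RB); classification runs
second, on the completed table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

# Extended Lipinski rule bounds (inclusive).
HBD_MAX = 5
HBA_MAX = 10
MW_MAX = 500.0
TPSA_MAX = 140.0
RB_MAX = 10
XLOGP3_MIN = -0.4
XLOGP3_MAX = 5.6

#: Predictors used for 1-NN imputation of XLogP3.
IMPUTE_PREDICTORS = ("mw", "tpsa", "hbd", "rb")


@dataclass
class MoleculeProperties:
    metabolite_id: str
    mw: Optional[float] = None
    tpsa: Optional[float] = None
    hbd: Optional[float] = None
    hba: Optional[float] = None
    rb: Optional[float] = None
    xlogp3: Optional[float] = None
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.mw is not None and not self.mw > 0:
            raise ValueError(f"{self.metabolite_id}: MW must be positive")
        for name in ("hbd", "hba", "rb"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.metabolite_id}: {name} must be >= 0")


def _is_missing(v: Optional[float]) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


# ---------------------------------------------------------------------------
# 1-NN imputation of XLogP3
# ---------------------------------------------------------------------------


def impute_xlogp3(
    train: Sequence[MoleculeProperties],
    queries: Sequence[MoleculeProperties],
    standardize: bool = True,
) -> tuple[list[MoleculeProperties], list[str]]:
    """Fill missing XLogP3 in `queries` from the single nearest training
    record under Euclidean distance on (MW, TPSA, HBD, RB).

    Predictors are z-scored with parameters fitted on the training set only
    (raw-scale mode via ``standardize=False``); distance ties are broken by
    the smallest metabolite id.  Queries missing any predictor are left
    unimputed and reported in the second return value.  Training records are
    never altered.
    """
    usable = [
        t for t in train
        if not any(_is_missing(getattr(t, p)) for p in IMPUTE_PREDICTORS)
        and not _is_missing(t.xlogp3)
    ]
    if not usable:
        raise ValueError("no usable training records (need all predictors + XLogP3)")
    usable = sorted(usable, key=lambda t: t.metabolite_id)
    X = np.array([[getattr(t, p) for p in IMPUTE_PREDICTORS] for t in usable], dtype=float)
    y = np.array([t.xlogp3 for t in usable], dtype=float)
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])
    Xs = (X - mean) / std

    out: list[MoleculeProperties] = []
    skipped: list[str] = []
    for q in queries:
        if any(_is_missing(getattr(q, p)) for p in IMPUTE_PREDICTORS):
            skipped.append(q.metabolite_id)
            out.append(replace(q))
            continue
        v = (np.array([getattr(q, p) for p in IMPUTE_PREDICTORS], dtype=float) - mean) / std
        d = np.linalg.norm(Xs - v, axis=1)
        best = np.flatnonzero(d <= d.min() + 1e-12)[0]  # rows sorted by id
        out.append(replace(q, xlogp3=float(y[best]), imputed=True))
    return out, skipped


# ---------------------------------------------------------------------------
# Rule classifier
# ---------------------------------------------------------------------------


def classify_permeable(props: MoleculeProperties) -> bool:
    """True iff every property is present (XLogP3 possibly imputed) and all
    six rules hold; any absent property classifies as not permeable."""
    values = (props.mw, props.tpsa, props.hbd, props.hba, props.rb, props.xlogp3)
    if any(_is_missing(v) for v in values):
        return False
    return (
        props.hbd <= HBD_MAX
        and props.hba <= HBA_MAX
        and props.mw <= MW_MAX
        and props.tpsa <= TPSA_MAX
        and props.rb <= RB_MAX
        and XLOGP3_MIN <= props.xlogp3 <= XLOGP3_MAX
    )


# ---------------------------------------------------------------------------
# Property table I/O and database annotation
# ---------------------------------------------------------------------------

_COLUMNS = ["metabolite_id", "MW", "TPSA", "HBD", "HBA", "RB", "XLogP3"]


def read_property_table(path: str) -> list[MoleculeProperties]:
    """Read a property TSV (metabolite_id, MW, TPSA, HBD, HBA, RB, XLogP3;
    empty cell = missing)."""
    df = pd.read_csv(path, sep="\t")
    return properties_from_frame(df)


def properties_from_frame(df: pd.DataFrame) -> list[MoleculeProperties]:
    out = []
    for _, row in df.iterrows():
        def get(col: str) -> Optional[float]:
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        out.append(
            MoleculeProperties(
                metabolite_id=str(row["metabolite_id"]),
                mw=get("MW"),
                tpsa=get("TPSA"),
                hbd=get("HBD"),
                hba=get("HBA"),
                rb=get("RB"),
                xlogp3=get("XLogP3"),
            )
        )
    return out


def properties_to_frame(records: Iterable[MoleculeProperties]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "metabolite_id": r.metabolite_id,
                "MW": r.mw,
                "TPSA": r.tpsa,
                "HBD": r.hbd,
                "HBA": r.hba,
                "RB": r.rb,
                "XLogP3": r.xlogp3,
                "imputed": r.imputed,
                "permeable": classify_permeable(r),
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS + ["imputed", "permeable"])


def permeable_metabolites(
    records: Sequence[MoleculeProperties], standardize: bool = True
) -> set[str]:
    """Impute missing XLogP3 from the complete records, then classify.

    Returns the set of metabolite ids predicted likely permeable.
    """
    train = [r for r in records if not _is_missing(r.xlogp3)]
    queries = [r for r in records if _is_missing(r.xlogp3)]
    if train and queries:
        imputed, _ = impute_xlogp3(train, queries, standardize=standardize)
    else:
        imputed = list(queries)
    completed = list(train) + imputed
    return {r.metabolite_id for r in completed if classify_permeable(r)}


def annotate_transport_permeability(db, permeable_ids: set[str]) -> set[str]:
    """Transport reactions in a gap-fill database that carry at least one
    permeable metabolite (these receive a reduced gap-filling cost)."""
    from .model_core import KIND_TRANSPORT

    out = set()
    for rxn in db.reactions.values():
        if rxn.kind != KIND_TRANSPORT:
            continue
        if any(mid in permeable_ids for (mid, _) in rxn.stoichiometry):
            out.add(rxn.id)
    return out
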