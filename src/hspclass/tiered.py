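"""The two-tier prediction schema and its persistence.

Tier 1 is a single binary gate separating heat shock proteins (HSPs) from
everything else.  Only gate-positive sequences reach tier 2, where six
one-vs-rest binary models — one per family HSP20/40/60/70/90/100 — each
score the sequence, and the family with the largest decision value wins
(ties broken by canonical family order).  When even the winning family
score is negative the verdict is flagged low-confidence rather than
refused: every gate-positive sequence receives exactly one family.

A trained predictor persists as a directory bundle: a JSON metadata
manifest plus one JSON parameter file per binary model, all plain text.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BundleError, EligibilityError, HspClassError
from .features import encode_dataset
from .sequence_io import ProteinRecord
from .svm import BinaryModel, KernelConfig, train_binary

#: the six HSP families in canonical (tie-break) order
FAMILIES: tuple[str, ...] = ("HSP20", "HSP40", "HSP60", "HSP70", "HSP90", "HSP100")

BUNDLE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Verdict:
    """Per-record prediction outcome.

    ``family`` and ``family_scores`` are present only when ``is_hsp`` is
    true; ``confidence`` is "low" when no family model scored positive.
    A record the predictor could not encode carries ``error`` instead.
    """

    record_id: str
    is_hsp: bool | None = None
    tier1_score: float | None = None
    family: str | None = None
    family_scores: dict[str, float] | None = None
    confidence: str | None = None
    error: str | None = None

    def __post_init__(self):
        if self.error is None and self.is_hsp is False:
            if self.family is not None or self.family_scores is not None:
                raise HspClassError("non-HSP verdicts must not carry a family")


@dataclass
class TieredPredictor:
    tier1: BinaryModel
    tier2: dict[str, BinaryModel]
    encoding: str
    tier1_threshold: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tier1.encoding != self.encoding:
            raise HspClassError("tier-1 model encoding does not match predictor encoding")
        for fam, model in self.tier2.items():
            if fam not in FAMILIES:
                raise HspClassError(f"unknown family {fam!r}")
            if model.encoding != self.encoding:
                raise HspClassError(f"family model {fam} encoding mismatch")

    @property
    def families(self) -> list[str]:
        return [f for f in FAMILIES if f in self.tier2]


def build_tier1(
    hsp_records: Sequence[ProteinRecord],
    non_hsp_records: Sequence[ProteinRecord],
    encoding: str = "coupled",
    config: KernelConfig | None = None,
    seed: int = 0,
) -> BinaryModel:
    """Train the HSP / non-HSP gate (HSP positive)."""
    if len(hsp_records) == 0 or len(non_hsp_records) == 0:
        raise HspClassError("both the HSP and non-HSP collections must be non-empty")
    config = config or KernelConfig.linear()
    records = list(hsp_records) + list(non_hsp_records)
    labels = [1] * len(hsp_records) + [-1] * len(non_hsp_records)
    X, y = encode_dataset(records, encoding=encoding, labels=labels)
    return train_binary(X, y, config, seed=seed, encoding=encoding, positive_label="HSP")


def build_tier2(
    family_records: Mapping[str, Sequence[ProteinRecord]],
    encoding: str = "coupled",
    per_family_config: Mapping[str, KernelConfig] | KernelConfig | None = None,
    seed: int = 0,
) -> dict[str, BinaryModel]:
    """Train one one-vs-rest model per family.

    For each family F the positives are F's records and the negatives the
    union of all other families' records.  Hyper-parameters may differ per
    family (pass a mapping) or be shared (pass one config or None).
    """
    fams = [f for f in FAMILIES if f in family_records]
    unknown = set(family_records) - set(FAMILIES)
    if unknown:
        raise HspClassError(f"unknown families {sorted(unknown)!r}")
    if len(fams) < 2:
        raise HspClassError("one-vs-rest training needs at least 2 families")
    for f in fams:
        if len(family_records[f]) == 0:
            raise HspClassError(f"family {f} has no records")

    all_records: list[ProteinRecord] = []
    fam_of: list[str] = []
    for f in fams:
        all_records.extend(family_records[f])
        fam_of.extend([f] * len(family_records[f]))
    X, _ = encode_dataset(all_records, encoding=encoding)
    fam_arr = np.asarray(fam_of)

    models: dict[str, BinaryModel] = {}
    for f in fams:
        if isinstance(per_family_config, Mapping):
            config = per_family_config.get(f) or KernelConfig.linear()
        else:
            config = per_family_config or KernelConfig.linear()
        y = np.where(fam_arr == f, 1, -1)
        models[f] = train_binary(
            X, y, config, seed=seed, encoding=encoding, positive_label=f
        )
    return models


def predict(
    records: Sequence[ProteinRecord], predictor: TieredPredictor
) -> list[Verdict]:
    """Run the two-tier schema over a record collection, order preserved.

    Encoding-ineligible records yield an error Verdict; the run continues.
    """
    if len(records) == 0:
        raise HspClassError("no records to predict")
    verdicts: list[Verdict | None] = [None] * len(records)
    eligible_idx: list[int] = []
    eligible: list[ProteinRecord] = []
    for i, rec in enumerate(records):
        if predictor.encoding == "coupled" and not rec.eligible_for_coupled:
            verdicts[i] = Verdict(
                record_id=rec.id, error="too short for coupled encoding"
            )
        else:
            eligible_idx.append(i)
            eligible.append(rec)
    if eligible:
        X, _ = encode_dataset(eligible, encoding=predictor.encoding)
        tier1_scores = predictor.tier1.decision_values(X)
        fams = predictor.families
        fam_scores = {f: predictor.tier2[f].decision_values(X) for f in fams}
        for row, (i, rec) in enumerate(zip(eligible_idx, eligible)):
            t1 = float(tier1_scores[row])
            if t1 >= predictor.tier1_threshold:
                scores = {f: float(fam_scores[f][row]) for f in fams}
                best = max(fams, key=lambda f: (scores[f], -fams.index(f)))
                verdicts[i] = Verdict(
                    record_id=rec.id,
                    is_hsp=True,
                    tier1_score=t1,
                    family=best,
                    family_scores=scores,
                    confidence="normal" if scores[best] >= 0 else "low",
                )
            else:
                verdicts[i] = Verdict(record_id=rec.id, is_hsp=False, tier1_score=t1)
    return list(verdicts)  # type: ignore[arg-type]


def verdicts_to_tsv(verdicts: Sequence[Verdict], sink: str | Path | IO[str]) -> None:
    """One TSV row per input record: id, gate outcome, scores, family, confidence."""
    rows = []
    for v in verdicts:
        row: dict = {"id": v.record_id}
        if v.error is not None:
            row.update(is_hsp="ERROR", tier1_score="", family="", confidence=v.error)
            for f in FAMILIES:
                row[f"score_{f}"] = ""
        else:
            row["is_hsp"] = str(bool(v.is_hsp)).lower()
            row["tier1_score"] = v.tier1_score
            row["family"] = v.family or ""
            for f in FAMILIES:
                row[f"score_{f}"] = (v.family_scores or {}).get(f, "")
            row["confidence"] = v.confidence or ""
        rows.append(row)
    cols = ["id", "is_hsp", "tier1_score", "family"] + [
        f"score_{f}" for f in FAMILIES
    ] + ["confidence"]
    pd.DataFrame(rows, columns=cols).to_csv(sink, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bundle persistence


def save_bundle(predictor: TieredPredictor, path: str | Path) -> None:
    """Write the predictor as a text bundle: manifest.json + one JSON per model."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "encoding": predictor.encoding,
        "tier1_threshold": predictor.tier1_threshold,
        "families": predictor.families,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "metadata": predictor.metadata,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (path / "tier1.json").write_text(json.dumps(predictor.tier1.to_dict()))
    for fam in predictor.families:
        (path / f"tier2_{fam}.json").write_text(
            json.dumps(predictor.tier2[fam].to_dict())
        )


def load_bundle(path: str | Path) -> TieredPredictor:
    """Load a bundle; errors name the missing or incompatible component."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.is_file():
        raise BundleError(f"bundle at {path} is missing manifest.json")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise BundleError(f"bundle manifest is corrupt: {exc}") from exc
    version = manifest.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise BundleError(
            f"bundle format version {version!r} is not supported "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    tier1_path = path / "tier1.json"
    if not tier1_path.is_file():
        raise BundleError("bundle is missing the tier-1 model (tier1.json)")
    tier1 = BinaryModel.from_dict(json.loads(tier1_path.read_text()))
    tier2: dict[str, BinaryModel] = {}
    for fam in manifest.get("families", []):
        model_path = path / f"tier2_{fam}.json"
        if not model_path.is_file():
            raise BundleError(f"bundle is missing the {fam} family model")
        tier2[fam] = BinaryModel.from_dict(json.loads(model_path.read_text()))
    return TieredPredictor(
        tier1=tier1,
        tier2=tier2,
        encoding=manifest["encoding"],
        tier1_threshold=float(manifest.get("tier1_threshold", 0.0)),
        metadata=manifest.get("metadata", {}),
    )
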