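"""Seeded synthetic protein corpora with controlled composition structure.

Sequences are drawn from first-order Markov chains over the 20-letter
alphabet, so residue *and* dipeptide statistics are controllable: a
residue bias multiplies the stationary weight of chosen residues, and a
dipeptide bias multiplies the transition probability of chosen ordered
pairs.  First-order chains (rather than i.i.d. residues) make the coupled
(dipeptide) encoding carry signal beyond the discrete composition, which
is exactly the regime the two-tier classifier is designed for.

The default benchmark emulates the class structure of a curated HSP
training corpus: six family classes plus a larger non-HSP background,
with counts scaled to one fifth of the 2,225-HSP / 10,000-non-HSP
original (minimum 12 per class).  The six HSP classes share a common
charged-residue enrichment (mirroring the compositional signature of real
chaperones) that separates them from the uniform background, while each
family carries its own dipeptide coupling pattern — a family-specific
"partner offset" boosting transitions from each residue to the residue a
fixed distance ahead in the alphabet — so family identity lives almost
entirely in sequence order, not in marginal composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, AA_INDEX, N_RESIDUES
from .errors import HspClassError
from .sequence_io import ProteinRecord
from .tiered import FAMILIES

#: per-class record counts: one fifth of the reference corpus shape
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "HSP20": 71,
    "HSP40": 256,
    "HSP60": 33,
    "HSP70": 57,
    "HSP90": 12,
    "HSP100": 17,
    "non-HSP": 2000,
}

#: (residue bias multiplier, dipeptide bias multiplier) per separation level
SEPARATION_LEVELS: dict[str, tuple[float, float]] = {
    "strong": (3.0, 8.0),
    "moderate": (1.8, 3.0),
    "weak": (1.2, 1.5),
}

#: residues jointly enriched in all synthetic HSP families (charged set)
HSP_BIAS_RESIDUES: tuple[str, ...] = ("K", "R", "D", "E")

#: family -> alphabet offset of the boosted transition partner
FAMILY_OFFSETS: dict[str, int] = {
    "HSP20": 1,
    "HSP40": 3,
    "HSP60": 5,
    "HSP70": 7,
    "HSP90": 9,
    "HSP100": 11,
}

DEFAULT_LENGTH_RANGE: tuple[int, int] = (50, 400)


@dataclass(frozen=True)
class FamilyGenerator:
    """A first-order Markov chain over the canonical alphabet."""

    name: str
    initial: np.ndarray  # (20,) probabilities
    transition: np.ndarray  # (20, 20) row-stochastic
    length_range: tuple[int, int]
    seed: int

    def __post_init__(self):
        if self.initial.shape != (N_RESIDUES,) or self.transition.shape != (
            N_RESIDUES,
            N_RESIDUES,
        ):
            raise HspClassError("generator distributions have wrong shape")
        if (self.initial < 0).any() or (self.transition < 0).any():
            raise HspClassError("generator probabilities must be non-negative")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise HspClassError("initial distribution must sum to 1")
        if np.abs(self.transition.sum(axis=1) - 1.0).max() > 1e-12:
            raise HspClassError("transition rows must each sum to 1")
        lo, hi = self.length_range
        if lo < 2 or lo > hi:
            raise HspClassError("length range must satisfy 2 <= min <= max")

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix at eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transition.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, k])
        v = np.abs(v)
        return v / v.sum()


def make_family_generator(
    name: str,
    residue_bias: Mapping[str, float] | None = None,
    dipeptide_bias: Mapping[str, float] | None = None,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    seed: int = 0,
) -> FamilyGenerator:
    """Construct a Markov generator from multiplicative bias specs.

    ``residue_bias`` maps residues to stationary-weight multipliers;
    ``dipeptide_bias`` maps ordered pairs (e.g. ``"AC"``) to transition
    multipliers.  With no bias the chain is uniform i.i.d. (all rows 1/20).
    """
    weights = np.ones(N_RESIDUES)
    for aa, mult in (residue_bias or {}).items():
        if aa not in AA_INDEX:
            raise HspClassError(f"unknown residue {aa!r} in bias spec")
        if mult < 0:
            raise HspClassError(f"negative bias multiplier for residue {aa!r}")
        weights[AA_INDEX[aa]] *= mult
    if weights.sum() == 0:
        raise HspClassError("residue bias removes all probability mass")

    transition = np.tile(weights, (N_RESIDUES, 1))
    for pair, mult in (dipeptide_bias or {}).items():
        if len(pair) != 2 or pair[0] not in AA_INDEX or pair[1] not in AA_INDEX:
            raise HspClassError(f"invalid dipeptide {pair!r} in bias spec")
        if mult < 0:
            raise HspClassError(f"negative bias multiplier for dipeptide {pair!r}")
        transition[AA_INDEX[pair[0]], AA_INDEX[pair[1]]] *= mult
    row_sums = transition.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        raise HspClassError("dipeptide bias removes all mass from a transition row")
    return FamilyGenerator(
        name=name,
        initial=weights / weights.sum(),
        transition=transition / row_sums,
        length_range=length_range,
        seed=seed,
    )


def sample_records(
    generator: FamilyGenerator, n: int, seed: int = 0
) -> list[ProteinRecord]:
    """Draw ``n`` records; lengths uniform over the range, residues by the chain.

    Identical (generator, n, seed) yield identical records.  Sampling is
    vectorised across records, advancing all chains one position per step.
    """
    if n < 1:
        raise HspClassError(f"need n >= 1 records, got {n}")
    rng = np.random.default_rng([generator.seed & 0x7FFFFFFF, seed & 0x7FFFFFFF])
    lo, hi = generator.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    max_len = int(lengths.max())
    cum_init = np.cumsum(generator.initial)
    cum_trans = np.cumsum(generator.transition, axis=1)
    u = rng.random((n, max_len))
    states = np.empty((n, max_len), dtype=np.intp)
    states[:, 0] = np.searchsorted(cum_init, u[:, 0], side="right")
    for t in range(1, max_len):
        rows = cum_trans[states[:, t - 1]]
        states[:, t] = (rows < u[:, t, None]).sum(axis=1)
    np.clip(states, 0, N_RESIDUES - 1, out=states)
    letters = np.array(list(AMINO_ACIDS))
    records = []
    for i in range(n):
        seq = "".join(letters[states[i, : lengths[i]]])
        records.append(ProteinRecord(id=f"{generator.name}_{i + 1}", residues=seq))
    return records


@dataclass(frozen=True)
class BenchmarkSpec:
    """Shape of a synthetic benchmark corpus.

    ``class_counts`` maps the six family names plus ``"non-HSP"`` to record
    counts; ``separation`` controls how divergent the generators are.
    """

    class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    separation: str = "strong"
    master_seed: int = 0
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE

    def __post_init__(self):
        if self.separation not in SEPARATION_LEVELS:
            raise HspClassError(
                f"separation must be one of {tuple(SEPARATION_LEVELS)}, "
                f"got {self.separation!r}"
            )
        unknown = set(self.class_counts) - set(FAMILIES) - {"non-HSP"}
        if unknown:
            raise HspClassError(f"unknown benchmark classes {sorted(unknown)!r}")
        for cls, count in self.class_counts.items():
            if count < 2:
                raise HspClassError(f"class {cls} needs at least 2 records, got {count}")


@dataclass
class Benchmark:
    """A labelled corpus: records plus generative tier-1 and family labels."""

    records: list[ProteinRecord]
    tier1_labels: np.ndarray  # +1 HSP, -1 background
    family_labels: list[str | None]  # family name, or None for background

    @property
    def hsp_records(self) -> list[ProteinRecord]:
        return [r for r, t in zip(self.records, self.tier1_labels) if t == 1]

    @property
    def non_hsp_records(self) -> list[ProteinRecord]:
        return [r for r, t in zip(self.records, self.tier1_labels) if t == -1]

    def by_family(self) -> dict[str, list[ProteinRecord]]:
        out: dict[str, list[ProteinRecord]] = {}
        for rec, fam in zip(self.records, self.family_labels):
            if fam is not None:
                out.setdefault(fam, []).append(rec)
        return {f: out[f] for f in FAMILIES if f in out}


def benchmark_generators(
    separation: str = "strong",
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    master_seed: int = 0,
) -> dict[str, FamilyGenerator]:
    """The seven class generators (six families + background) for one level."""
    residue_mult, dipeptide_mult = SEPARATION_LEVELS[separation]
    gens: dict[str, FamilyGenerator] = {
        "non-HSP": make_family_generator(
            "non-HSP", length_range=length_range, seed=master_seed
        )
    }
    charged = {aa: residue_mult for aa in HSP_BIAS_RESIDUES}
    for k, fam in enumerate(FAMILIES):
        offset = FAMILY_OFFSETS[fam]
        pairs = {
            AMINO_ACIDS[a] + AMINO_ACIDS[(a + offset) % N_RESIDUES]: dipeptide_mult
            for a in range(N_RESIDUES)
        }
        gens[fam] = make_family_generator(
            fam,
            residue_bias=charged,
            dipeptide_bias=pairs,
            length_range=length_range,
            seed=master_seed + k + 1,
        )
    return gens


def make_benchmark(spec: BenchmarkSpec | None = None) -> Benchmark:
    """Sample a labelled corpus with the spec's per-class counts, exactly."""
    spec = spec or BenchmarkSpec()
    gens = benchmark_generators(
        spec.separation, spec.length_range, spec.master_seed
    )
    records: list[ProteinRecord] = []
    tier1: list[int] = []
    fams: list[str | None] = []
    ordered = [f for f in FAMILIES if f in spec.class_counts]
    if "non-HSP" in spec.class_counts:
        ordered.append("non-HSP")
    for cls in ordered:
        recs = sample_records(gens[cls], spec.class_counts[cls], seed=spec.master_seed)
        records.extend(recs)
        if cls == "non-HSP":
            tier1.extend([-1] * len(recs))
            fams.extend([None] * len(recs))
        else:
            tier1.extend([1] * len(recs))
            fams.extend([cls] * len(recs))
    return Benchmark(
        records=records,
        tier1_labels=np.asarray(tier1),
        family_labels=fams,
    )


def write_manifest(
    benchmark: Benchmark, sink: str | Path | IO[str]
) -> None:
    """TSV label manifest: id, tier1_label (HSP / non-HSP), family_label."""
    pd.DataFrame(
        {
            "id": [r.id for r in benchmark.records],
            "tier1_label": [
                "HSP" if t == 1 else "non-HSP" for t in benchmark.tier1_labels
            ],
            "family_label": [f or "" for f in benchmark.family_labels],
        }
    ).to_csv(sink, sep="\t", index=False)


def read_manifest(source: str | Path | IO[str]) -> pd.DataFrame:
    """Read a label manifest (two or three columns; see :func:`write_manifest`)."""
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    if "id" not in df.columns:
        raise HspClassError("label manifest must have an 'id' column")
    if "family_label" not in df.columns and "tier1_label" not in df.columns:
        raise HspClassError(
            "label manifest needs a 'tier1_label' and/or 'family_label' column"
        )
    return df
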