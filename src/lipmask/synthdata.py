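"""Synthetic linkage scenarios.

Generates a (target file, identification file, truth) triple with a known
overlap, emulating the statistical structure of two classic audit
scenarios: a facility registry with a short categorical code as
quasi-identifier (two-character truncated facility codes, 20-symbol
alphabet), and a population file with sex and age. Units are placed
uniformly in the study region; overlapping units carry identical
coordinates and quasi-identifiers in both files (the adversary's
perfect-knowledge assumption: no measurement error, no missing values).

Quasi-identifiers are drawn independently of location, so the expected
candidate-graph size has a closed form used as a sizing guard: the true
overlap pairs always match, and each of the remaining cross pairs collides
with probability 1/|alphabet| (facility codes) or 1/(2*73) (sex uniform on
two levels, age uniform on 18..90).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attack import CandidateVertex
from .geometry import Region, sample_uniform_latlon
from .microdata import MicrodataTable
from .rng import substream

__all__ = [
    "ScenarioSpec",
    "default_region",
    "generate_file_pair",
    "expected_candidate_count",
    "FACILITY_CODES",
    "AGE_RANGE",
]

#: 20-symbol alphabet emulating two-character truncated facility codes.
FACILITY_CODES = tuple(f"R{c}" for c in "ABCDEFGHJKLMNPQRSTVW")

#: Inclusive uniform age range for the sex-age scheme.
AGE_RANGE = (18, 90)

_SCHEMES = ("facility-code", "sex-age")


def default_region() -> Region:
    """A mid-latitude ~6 deg x 8 deg rectangle (lat 47..53, lon 6..14)."""
    return Region.from_bbox(47.0, 53.0, 6.0, 14.0)


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic two-file linkage scenario."""

    n_target: int
    n_ident: int
    n_overlap: int
    qid_scheme: str = "sex-age"
    region: Region = field(default_factory=default_region)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_target, self.n_ident) < 1 or self.n_overlap < 0:
            raise ValueError("file sizes must be >= 1 and overlap >= 0")
        if self.n_overlap > min(self.n_target, self.n_ident):
            raise ValueError("overlap cannot exceed either file size")
        if self.qid_scheme not in _SCHEMES:
            raise ValueError(f"qid_scheme must be one of {_SCHEMES}")

    @property
    def qid_names(self) -> list[str]:
        return ["facility_code"] if self.qid_scheme == "facility-code" else ["sex", "age"]


def _draw_qids(scheme: str, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    if scheme == "facility-code":
        return {"facility_code": rng.choice(FACILITY_CODES, size=n)}
    lo, hi = AGE_RANGE
    return {
        "sex": rng.choice(["F", "M"], size=n),
        "age": rng.integers(lo, hi + 1, size=n),
    }


def generate_file_pair(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> tuple[MicrodataTable, MicrodataTable, set[CandidateVertex]]:
    """Generate (target, ident, truth) for the scenario.

    Draws n_target + n_ident - n_overlap distinct units uniformly in the
    region; the first n_overlap units appear in both files with identical
    coordinates and quasi-identifiers. Row order within each file is
    shuffled so position leaks nothing. truth is the set of
    (target-id, ident-id) pairs for the overlapping units.
    """
    if rng is None:
        rng = substream(spec.seed, "synthetic-data")
    n_units = spec.n_target + spec.n_ident - spec.n_overlap
    latlon = sample_uniform_latlon(spec.region, n_units, rng)
    qids = _draw_qids(spec.qid_scheme, n_units, rng)

    # units [0, n_overlap) are shared; target then takes [0, n_target),
    # ident takes the shared block plus the remaining units
    t_units = np.arange(spec.n_target)
    i_units = np.concatenate(
        [np.arange(spec.n_overlap), np.arange(spec.n_target, n_units)]
    ).astype(int)

    def build(prefix: str, units: np.ndarray) -> tuple[MicrodataTable, dict[int, str]]:
        # shuffle rows and number ids positionally so the id token carries
        # no information about which unit (and hence which counterpart row)
        # a record refers to
        order = rng.permutation(len(units))
        units = units[order]
        ids = [f"{prefix}{row:05d}" for row in range(len(units))]
        df = pd.DataFrame({"id": ids})
        for name, col in qids.items():
            df[name] = col[units]
        df["lat"] = latlon[units, 0]
        df["lon"] = latlon[units, 1]
        return MicrodataTable(df), {int(u): rid for u, rid in zip(units, ids)}

    target, t_map = build("T", t_units)
    ident, i_map = build("I", i_units)
    truth = {CandidateVertex(t_map[u], i_map[u]) for u in range(spec.n_overlap)}
    return target, ident, truth


def expected_candidate_count(spec: ScenarioSpec) -> float:
    """Analytic expectation of the candidate-set size |V| under the
    scheme's uniform-independence model: the n_overlap true pairs always
    agree, and each of the other cross pairs collides with the scheme's
    uniform collision probability."""
    if spec.qid_scheme == "facility-code":
        p = 1.0 / len(FACILITY_CODES)
    else:
        lo, hi = AGE_RANGE
        p = 1.0 / (2 * (hi - lo + 1))
    cross = spec.n_target * spec.n_ident - spec.n_overlap
    return spec.n_overlap + cross * p
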