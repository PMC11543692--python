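"""Consensus aggregation scoring (0-5) from per-residue predictor tracks.

Each external predictor (TANGO, WALTZ, FoldAmyloid, Aggrescan, PASTA 2.0)
produces one value per residue; a threshold rule turns values into hits, and
the consensus is simply the per-residue count of predictors calling a hit.
Thresholds are strict inequalities: a value exactly at the cutoff is not a
hit. Run-length rules (FoldAmyloid) require the raw criterion to hold over a
minimum number of consecutive residues before any of them counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .model import FibrilModel, SequenceRecord


@dataclass(frozen=True)
class ThresholdRule:
    direction: str  # "above" | "below"
    cutoff: float
    min_run: int = 1

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ConfigurationError(f"unknown rule direction {self.direction!r}")
        if self.min_run < 1:
            raise ConfigurationError("min_run must be >= 1")


@dataclass
class ScoreTrack:
    predictor: str
    values: np.ndarray
    rule: ThresholdRule

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rule is None:
            raise ConfigurationError(f"track {self.predictor!r} has no threshold rule")


#: The study's predictor settings. Aggrescan publishes no fixed numeric
#: cutoff; its hot-spot threshold travels in the track file header (override
#: here or in config).
PAPER_RULES: dict[str, ThresholdRule] = {
    "tango": ThresholdRule("above", 0.1),
    "waltz": ThresholdRule("above", 75.0),
    "foldamyloid": ThresholdRule("above", 0.062, min_run=5),
    "aggrescan": ThresholdRule("above", -0.02),
    "pasta": ThresholdRule("below", -2.8),
}

CONSENSUS_COLORS = {0: "#2166ac", 1: "#67a9cf", 2: "#d1e5f0",
                    3: "#fddbc7", 4: "#ef8a62", 5: "#b2182b"}


def hit_mask(track: ScoreTrack) -> np.ndarray:
    """Boolean per-residue hit mask under the track's threshold rule."""
    rule = track.rule
    if rule.direction == "above":
        raw = track.values > rule.cutoff
    else:
        raw = track.values < rule.cutoff
    if rule.min_run <= 1:
        return raw
    mask = np.zeros_like(raw)
    n = len(raw)
    i = 0
    while i < n:
        if raw[i]:
            j = i
            while j < n and raw[j]:
                j += 1
            if j - i >= rule.min_run:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


@dataclass
class ConsensusProfile:
    values: np.ndarray  # integer 0..n_tracks per residue
    n_tracks: int
    predictors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)

    def colors(self) -> list[str]:
        return [CONSENSUS_COLORS.get(min(int(v), 5), "#000000") for v in self.values]

    def __len__(self) -> int:
        return len(self.values)


def consensus(tracks: Sequence[ScoreTrack]) -> ConsensusProfile:
    """Per-residue count of predictors calling a hit."""
    if not tracks:
        raise ConfigurationError("need at least one score track")
    lengths = {len(t.values) for t in tracks}
    if len(lengths) != 1:
        raise ConfigurationError(f"track length mismatch: {sorted(lengths)}")
    total = np.zeros(lengths.pop(), dtype=int)
    for t in tracks:
        total += hit_mask(t).astype(int)
    return ConsensusProfile(total, n_tracks=len(tracks),
                            predictors=[t.predictor for t in tracks])


#: Kyte-Doolittle hydropathy, the default propensity scale for the built-in
#: sliding-window stand-in track generator.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def scale_window_score(
    sequence: SequenceRecord,
    scale: Optional[dict[str, float]] = None,
    window: int = 5,
    predictor: str = "scale",
    rule: Optional[ThresholdRule] = None,
) -> ScoreTrack:
    """Centered moving average of a per-residue propensity scale.

    A simple stand-in for external aggregation predictors: not their model,
    just a sliding-window scale score usable wherever a ScoreTrack is needed.
    Edges use shrinking windows so the track has full length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    scale = KYTE_DOOLITTLE if scale is None else scale
    missing = sorted({c for c in sequence.residues if c not in scale})
    if missing:
        raise ConfigurationError(f"scale lacks residues {missing}")
    raw = np.array([scale[c] for c in sequence.residues], dtype=float)
    half = window // 2
    n = len(raw)
    vals = np.array([raw[max(0, i - half): min(n, i + half + 1)].mean() for i in range(n)])
    if rule is None:
        rule = ThresholdRule("above", float(np.median(vals)))
    return ScoreTrack(predictor, vals, rule)


def map_to_structure(profile: ConsensusProfile, model: FibrilModel) -> FibrilModel:
    """Write the consensus value into the B-factor column of every layer.

    Returns an annotated copy; writing it out and recoloring by B-factor
    reproduces the structure coloring of the consensus analysis.
    """
    out = model.copy()
    for lay in out.layers:
        if len(lay.residues) != len(profile):
            raise ConfigurationError(
                f"profile length {len(profile)} != {len(lay.residues)} residues "
                f"in chain {lay.chain_id}"
            )
        for res, v in zip(lay.residues, profile.values):
            for a in res.atoms:
                a.b_iso = float(v)
    return out


def profile_from_structure(model: FibrilModel, layer: int = 0) -> ConsensusProfile:
    """Recover a consensus profile from an annotated structure's B-factors."""
    lay = model.layers[layer]
    vals = [int(round(res.atoms[0].b_iso)) for res in lay.residues]
    return ConsensusProfile(np.array(vals), n_tracks=max(vals, default=0))


def read_track(path: str | Path) -> ScoreTrack:
    """Read a 2-column (residue_seq, value) track file.

    The header line carries the predictor name and rule, e.g.::

        # predictor=tango rule=above cutoff=0.1 min_run=1
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            parts = line.replace(",", "\t").split()
            rows.append((int(parts[0]), float(parts[1])))
    if "predictor" not in meta:
        raise ConfigurationError(f"{path}: header does not name a predictor")
    name = meta["predictor"].lower()
    if "rule" in meta and "cutoff" in meta:
        rule = ThresholdRule(meta["rule"], float(meta["cutoff"]),
                             int(meta.get("min_run", 1)))
    elif name in PAPER_RULES:
        rule = PAPER_RULES[name]
    else:
        raise ConfigurationError(f"{path}: no threshold rule in header and no default "
                                 f"for predictor {name!r}")
    rows.sort(key=lambda r: r[0])
    return ScoreTrack(name, np.array([v for _, v in rows]), rule)


def write_track(track: ScoreTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        r = track.rule
        fh.write(f"# predictor={track.predictor} rule={r.direction} "
                 f"cutoff={r.cutoff} min_run={r.min_run}\n")
        for i, v in enumerate(track.values, start=1):
            fh.write(f"{i}\t{v:.6g}\n")


def with_rule(track: ScoreTrack, rule: ThresholdRule) -> ScoreTrack:
    """A copy of the track under a different threshold rule (config override)."""
    return ScoreTrack(track.predictor, track.values.copy(), rule)
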