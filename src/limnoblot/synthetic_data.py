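"""Synthetic survey generator: habitats, niche-structured scores, sequences.

Emulates a large standing-freshwater survey screened with a group-specific
probe panel: habitats spanning pH 3.8–9.1 with correlated physicochemical
covariates and Central-European-like coordinates; ordinal 0–3 detection
scores produced by latent Gaussian (unimodal or bimodal) pH niche responses
plus noise; and ITS-like ~1,900 bp sequences with the primer pair planted at
the ends and one concrete probe site planted internally.  Every generator is
fully deterministic under a fixed seed, and the generating parameters are
exported as a truth object so parameter-recovery tests can close the loop.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .probe_kit import (
    ITSRecord,
    PrimerPair,
    Probe,
    expand_sequence,
    load_builtin_primer_pairs,
    load_builtin_probes,
    reverse_complement,
    write_fasta,
)
from .score_data import HabitatTable, ScoreMatrix

__all__ = [
    "NicheSpec",
    "ScoreModel",
    "SyntheticTruth",
    "SyntheticBundle",
    "default_niches",
    "generate_habitats",
    "generate_scores",
    "generate_sequences",
    "generate_dataset",
    "suitability",
]


@dataclass(frozen=True)
class NicheSpec:
    """Latent pH niche of one probe-defined group.

    ``optima``: 1 (unimodal) or 2 (bimodal) pH optima; ``tolerance``: σ of
    the Gaussian response; ``amplitude``: peak suitability in (0,1] (0 marks
    a group that the panel never detects); ``baseline``: spurious weak-
    detection rate in [0, 0.05] mimicking faint cross-reactions.
    """

    name: str
    optima: tuple[float, ...]
    tolerance: float
    amplitude: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if len(self.optima) not in (1, 2):
            raise ValueError(f"{self.name}: need 1 or 2 optima")
        if not all(3.0 <= mu <= 10.0 for mu in self.optima):
            raise ValueError(f"{self.name}: optima must lie in [3.0, 10.0]")
        if not self.tolerance > 0:
            raise ValueError(f"{self.name}: tolerance must be > 0")
        if len(self.optima) == 2 and abs(self.optima[0] - self.optima[1]) < 2 * self.tolerance:
            raise ValueError(f"{self.name}: bimodal optima must differ by >= 2·tolerance")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"{self.name}: amplitude must be in [0, 1]")
        if not 0.0 <= self.baseline <= 0.05:
            raise ValueError(f"{self.name}: baseline must be in [0, 0.05]")


@dataclass(frozen=True)
class ScoreModel:
    """Maps latent suitability + Gaussian noise to ordinal scores 0–3."""

    thresholds: tuple[float, float, float] = (0.25, 0.5, 0.75)
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        t1, t2, t3 = self.thresholds
        if not (0 < t1 < t2 < t3 < 1):
            raise ValueError("thresholds must be strictly increasing within (0,1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def suitability(spec: NicheSpec, ph: np.ndarray) -> np.ndarray:
    """amplitude · max over optima of exp(−(pH−μ)²/(2σ²)).

    Bimodal niches take the max (not the sum) of the two Gaussians so the
    response stays within (0, amplitude].
    """
    ph = np.asarray(ph, dtype=float)
    resp = np.zeros_like(ph)
    for mu in spec.optima:
        resp = np.maximum(resp, np.exp(-((ph - mu) ** 2) / (2 * spec.tolerance**2)))
    return spec.amplitude * resp


def default_niches() -> list[NicheSpec]:
    """18 niche archetypes mirroring the probe panel's observed ecology.

    Alkaline-skewed optima (most groups prefer alkaline habitats, one is
    strictly acidic), several narrow alkaline groups, one circumneutral
    narrow group, bimodal groups with optima near pH 5.5 and 8.5, broad
    generalists, and four silent groups the panel never detects.
    """
    return [
        NicheSpec("Lim1+", (7.0,), 0.35, 0.95),
        NicheSpec("Lim2+", (8.2,), 0.55, 0.9),
        NicheSpec("Lim3+", (5.5, 8.5), 0.45, 0.85),
        NicheSpec("Lim4AusCurv+Lim3+", (5.6, 8.4), 0.5, 0.9),
        NicheSpec("Lim4AusCurv", (5.5, 8.5), 0.5, 1.0),
        NicheSpec("Lim5+", (7.0,), 0.5, 0.0),
        NicheSpec("Lim6+A", (7.0,), 0.5, 0.0, baseline=0.01),
        NicheSpec("Lim6+B", (8.0,), 0.4, 0.45),
        NicheSpec("Lim7+A", (7.0,), 0.5, 0.0, baseline=0.01),
        NicheSpec("Lim7+B", (8.2,), 0.4, 0.8),
        NicheSpec("Lim7+C", (8.3,), 0.4, 0.75),
        NicheSpec("Lim7+D", (8.1,), 0.45, 0.7),
        NicheSpec("Lim8Parv+", (5.7,), 1.2, 0.8),
        NicheSpec("Lim9Plankt+", (7.0,), 0.5, 0.0),
        NicheSpec("Lim10+", (6.5,), 2.0, 0.7),
        NicheSpec("Lim11+", (5.3, 8.3), 0.5, 0.85),
        NicheSpec("Lim12+A", (5.0,), 0.6, 0.9),
        NicheSpec("Lim13+", (8.3,), 0.6, 0.85),
    ]


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to regenerate (and verify recovery of) a dataset."""

    niches: tuple[NicheSpec, ...]
    score_model: ScoreModel
    n_habitats: int
    ph_range: tuple[float, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "niches": [asdict(n) for n in self.niches],
            "score_model": asdict(self.score_model),
            "n_habitats": self.n_habitats,
            "ph_range": list(self.ph_range),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            niches=tuple(
                NicheSpec(
                    n["name"], tuple(n["optima"]), n["tolerance"], n["amplitude"], n["baseline"]
                )
                for n in d["niches"]
            ),
            score_model=ScoreModel(tuple(d["score_model"]["thresholds"]), d["score_model"]["noise_sd"]),
            n_habitats=d["n_habitats"],
            ph_range=tuple(d["ph_range"]),
            seed=d["seed"],
        )


def generate_habitats(
    n: int, seed: int, ph_range: tuple[float, float] = (3.8, 9.1)
) -> HabitatTable:
    """Draw ``n`` standing-freshwater habitats with correlated covariates.

    pH is a uniform mixture: 70% spanning the whole range plus two equal
    narrower components (acidic bog-pond-like and alkaline fishpond-like
    sites), keeping coverage of the gradient roughly even while habitat
    types still cluster.  Conductivity is log-normal and rises with
    pH; oxygen falls as the DOC proxy (absorbance) rises via a shared humic
    latent factor; altitude is independent; coordinates fall in a Central-
    European box with mild spatial clustering of similar habitats.
    """
    if n < 1:
        raise ValueError("generate_habitats: n must be >= 1")
    lo, hi = ph_range
    if not (0 <= lo < hi <= 14):
        raise ValueError(f"invalid pH range {ph_range}")
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n, p=(0.7, 0.15, 0.15))
    draws = np.column_stack(
        [
            rng.uniform(lo, hi, n),
            rng.uniform(lo, min(hi, lo + 0.4 * (hi - lo)), n),
            rng.uniform(max(lo, hi - 0.4 * (hi - lo)), hi, n),
        ]
    )
    ph = draws[np.arange(n), comp]
    # conductivity (µS/cm): log-normal, positively tied to pH
    cond = np.exp(4.2 + 0.45 * (ph - 6.0) + rng.normal(0, 0.5, n))
    humic = rng.normal(0, 1, n)  # shared latent: humic/DOC load
    absorb = np.exp(-1.2 + 0.8 * humic + rng.normal(0, 0.2, n))
    oxygen = np.clip(9.0 - 1.8 * humic + rng.normal(0, 0.8, n), 0.05, None)
    altitude = np.clip(rng.normal(500, 180, n), 100, 2500)
    temperature = np.clip(rng.normal(17, 4, n), 1, 30)
    # three loose geographic clusters, alkaline sites slightly east
    centers = np.array([[48.2, 14.3], [49.1, 15.5], [48.8, 16.4]])
    which = np.clip(np.digitize(ph, [5.5, 7.5]), 0, 2)
    lat = centers[which, 0] + rng.normal(0, 0.6, n)
    lon = centers[which, 1] + rng.normal(0, 0.9, n)
    df = pd.DataFrame(
        {
            "pH": np.round(ph, 2),
            "conductivity": np.round(cond, 1),
            "oxygen": np.round(oxygen, 2),
            "absorbance": np.round(absorb, 4),
            "altitude": np.round(altitude, 0),
            "temperature": np.round(temperature, 1),
            "latitude": np.round(lat, 5),
            "longitude": np.round(lon, 5),
        },
        index=pd.Index([f"H{i + 1:03d}" for i in range(n)], name="habitat_id"),
    )
    return HabitatTable(df)


def generate_scores(
    habitats: HabitatTable,
    niches: list[NicheSpec] | tuple[NicheSpec, ...],
    model: ScoreModel = ScoreModel(),
    seed: int = 0,
) -> ScoreMatrix:
    """Ordinal 0–3 scores from latent niche responses plus noise.

    y = suitability(pH) + N(0, noise_sd); the score is the number of
    thresholds below y; with probability ``baseline`` a habitat additionally
    gets at least a weak (score 1) spurious detection.  Noise models
    variability of a real hybridization signal, so a group whose probe
    yields no signal at all (amplitude 0) stays at score 0 apart from its
    baseline false-positive rate.
    """
    rng = np.random.default_rng(seed)
    ph = habitats.ph.to_numpy(float)
    n = len(ph)
    t = np.asarray(model.thresholds)
    cols = {}
    for spec in niches:
        y = suitability(spec, ph)
        noise = rng.normal(0, 1, n)  # one draw per group keeps streams aligned
        if model.noise_sd > 0 and spec.amplitude > 0:
            y = y + model.noise_sd * noise
        score = (y[:, None] > t[None, :]).sum(axis=1)
        if spec.baseline > 0:
            spurious = rng.random(n) < spec.baseline
            score = np.maximum(score, spurious.astype(int))
        else:
            rng.random(n)
        cols[spec.name] = score
    df = pd.DataFrame(cols, index=habitats.df.index)
    return ScoreMatrix(df)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _concrete(rng: np.random.Generator, degenerate: str) -> str:
    options = expand_sequence(degenerate)
    return options[rng.integers(0, len(options))]


def generate_sequences(
    groups: list[str],
    probes: list[Probe],
    pair: PrimerPair,
    seed: int = 0,
    length: int = 1900,
) -> list[ITSRecord]:
    """ITS-like records: primer sites at the ends, one probe site inside.

    Each record is ``length`` bases: a concrete expansion of the forward
    primer at position 0, the reverse complement of a concrete expansion of
    the reverse primer at the very end (so the genus-specific amplicon spans
    the whole record), and — for groups with a probe of the same name —
    exactly one concrete expansion of that probe planted internally.
    """
    by_name = {p.name: p for p in probes}
    rng = np.random.default_rng(seed)
    min_len = len(pair.forward) + len(pair.reverse) + max((len(p) for p in probes), default=0) + 20
    if length < min_len:
        raise ValueError(f"record length {length} too short for primers and probes")
    records = []
    for group in groups:
        fwd = _concrete(rng, pair.forward)
        rev_site = reverse_complement(_concrete(rng, pair.reverse))
        core_len = length - len(fwd) - len(rev_site)
        core = _random_bases(rng, core_len)
        probe = by_name.get(group)
        if probe is not None:
            site = _concrete(rng, probe.sequence)
            pos = int(rng.integers(10, core_len - len(site) - 10))
            core = core[:pos] + site + core[pos + len(site):]
        records.append(ITSRecord(id=f"SYN_{group}", sequence=fwd + core + rev_site, group_label=group))
    return records


@dataclass
class SyntheticBundle:
    """One complete synthetic study: inputs plus generating truth."""

    habitats: HabitatTable
    scores: ScoreMatrix
    records: list[ITSRecord] = field(default_factory=list)
    truth: SyntheticTruth | None = None


def generate_dataset(
    out_dir: str | Path | None = None,
    n_habitats: int = 161,
    seed: int = 0,
    niches: list[NicheSpec] | None = None,
    score_model: ScoreModel = ScoreModel(),
    ph_range: tuple[float, float] = (3.8, 9.1),
    with_sequences: bool = True,
) -> SyntheticBundle:
    """Generate a full fixture: habitat table, score matrix, sequences, truth.

    Sub-generators draw from seeds derived deterministically from ``seed``.
    When ``out_dir`` is given, writes habitats.tsv, scores.tsv,
    sequences.fasta and truth.json there.
    """
    niches = list(niches) if niches is not None else default_niches()
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    habitats = generate_habitats(n_habitats, seed=sub[0], ph_range=ph_range)
    scores = generate_scores(habitats, niches, score_model, seed=sub[1])
    records: list[ITSRecord] = []
    if with_sequences:
        probes = load_builtin_probes()
        pair = load_builtin_primer_pairs()["Lim-ITS"]
        known = {p.name for p in probes}
        groups = [n.name for n in niches if n.name in known] or [p.name for p in probes]
        records = generate_sequences(groups, probes, pair, seed=sub[2])
    truth = SyntheticTruth(
        niches=tuple(niches),
        score_model=score_model,
        n_habitats=n_habitats,
        ph_range=ph_range,
        seed=seed,
    )
    bundle = SyntheticBundle(habitats, scores, records, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        habitats.write(out / "habitats.tsv")
        scores.write(out / "scores.tsv")
        if records:
            write_fasta(records, out / "sequences.fasta")
        truth.to_json(out / "truth.json")
    return bundle
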