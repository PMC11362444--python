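"""Synthetic questionnaire studies with ability-dependent lapse contamination.

The generator emulates a survey panel in which ordinal multi-item scales are
answered by persons whose latent traits drive a graded response model, but
where occasional *attentional lapses* replace the model-implied response with
an off-model draw.  The lapse probability for person i on item j is

    pi_ij = logistic(lambda0 + lambda1 * g_i + lambda2 * c_j
                     + lambda3 * g_i * c_j + omega_i),

with g the person's general ability (standard normal), c_j the item's
complexity score (0-9), and omega_i a stable person-level lapse propensity.
A negative ability slope makes lapses rarer for able persons (producing the
worst-performance-rule pattern downstream); a negative interaction makes the
ability-error association stronger for complex items (the task-complexity
pattern).  Under a lapse the response is uniform over the categories (or an
endpoint draw under the "extreme" contamination variant).

Cognitive ability is observed through four discretized subtests (two recall
tests 0-10 with a shared residual, serial sevens 0-5, backward counting 0-2)
whose sum is a 0-27 composite.  Multi-wave panels share person latents across
waves at a configurable retest correlation with exchangeable structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import betabinom

from .complexity import INDICATOR_COLUMNS
from .irt import ItemParameters, cumulative_probabilities

__all__ = [
    "SimulationConfig",
    "PersonSample",
    "StudyData",
    "generate_item_bank",
    "generate_persons",
    "generate_responses",
    "generate_cognitive_subtests",
    "generate_panel",
    "simulate_study",
    "default_complexity_distribution",
]

# item counts of the 21 multi-item scales (102 items total)
DEFAULT_SCALE_SIZES = (5, 5, 6, 4, 3, 4, 4, 5, 5, 4, 5, 3, 4, 5, 5, 5, 7, 7, 5, 4, 7)

# text synthesis vocabulary: fillers are on the familiar-word list and in no
# lexical category; each trigger activates exactly one category and is itself
# a familiar word, so DC is controlled solely by the rare words
_FILLERS = ("i", "feel", "good", "about", "my", "life", "most", "of", "the",
            "time", "people", "here", "are", "kind", "to", "me", "every",
            "day", "at", "home", "with", "family", "in", "this", "place")
_TRIGGERS = {"CON": "because", "NEG": "never", "DIS": "should",
             "TEN": "perhaps", "EXC": "instead"}
_RARE_WORDS = ("quixotic", "perfunctory")

_SUBTESTS = (
    # name, max, target mean, target sd, loading on g, shares recall residual
    ("immediate_recall", 10, 5.5, 1.8, 0.75, True),
    ("delayed_recall", 10, 4.6, 2.0, 0.75, True),
    ("serial7", 5, 3.3, 1.6, 0.60, False),
    ("backward_count", 2, 1.8, 0.45, 0.45, False),
)


def default_complexity_distribution() -> tuple[float, ...]:
    """Beta-binomial(9, 0.85, 1.51) over 0..9: mean ~3.25, SD ~2.65,
    matching a realistically overdispersed complexity composite."""
    return tuple(betabinom.pmf(np.arange(10), 9, 0.85, 1.51))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study.  Defaults are the study conditions
    the analyses assume (a scaled-down panel: 2000 persons, 21 scales with
    102 items, 3-7 categories)."""

    n_persons: int = 2000
    scale_sizes: tuple = DEFAULT_SCALE_SIZES
    categories_range: tuple = (3, 7)
    ability_theta_corr: float = 0.2
    lapse_intercept: float = -3.2
    lapse_ability_slope: float = -0.5
    lapse_complexity_slope: float = 0.1
    lapse_interaction: float = -0.05
    lapse_person_sd: float = 0.5
    contamination: str = "uniform"  # or "extreme"
    complexity_distribution: tuple = field(default_factory=default_complexity_distribution)
    recall_residual_corr: float = 0.4
    missing_rate: float = 0.0
    n_waves: int = 1
    wave_retest_corr: float = 0.7
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_persons < 2:
            raise ValueError("n_persons must be >= 2")
        lo, hi = self.categories_range
        if not (3 <= lo <= hi <= 7):
            raise ValueError("category counts must lie in 3..7")
        if not -1 <= self.ability_theta_corr <= 1:
            raise ValueError("ability_theta_corr must be in [-1, 1]")
        if not 0 <= self.wave_retest_corr <= 1:
            raise ValueError("wave_retest_corr must be in [0, 1]")
        if not -1 <= self.recall_residual_corr <= 1:
            raise ValueError("recall_residual_corr must be in [-1, 1]")
        if self.contamination not in ("uniform", "extreme"):
            raise ValueError("contamination must be 'uniform' or 'extreme'")
        p = np.asarray(self.complexity_distribution, dtype=float)
        if len(p) != 10 or np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError("complexity_distribution must be 10 probabilities over 0..9")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")

    @property
    def n_scales(self) -> int:
        return len(self.scale_sizes)

    @property
    def n_items(self) -> int:
        return int(sum(self.scale_sizes))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class PersonSample:
    """Latent person records for one wave."""

    persons: pd.DataFrame          # person_id, g, lapse_offset
    scale_thetas: np.ndarray       # (n_persons, n_scales)
    scale_ids: list

    @property
    def g(self) -> np.ndarray:
        return self.persons["g"].to_numpy()

    @property
    def lapse_offset(self) -> np.ndarray:
        return self.persons["lapse_offset"].to_numpy()


def _synthesize_text(active: dict, rng: np.random.Generator) -> str:
    """Build an item wording realizing the given lexical indicator pattern
    (WC, DC, CON, NEG, DIS, TEN, EXC)."""
    words = ["i", "feel"]
    for cat, trigger in _TRIGGERS.items():
        if active.get(cat, 0):
            words.append(trigger)
    if active.get("DC", 0):
        words.extend(_RARE_WORDS)
    if active.get("WC", 0):
        target = 10 + int(rng.integers(0, 4))
        k = 2
        while len(words) < target:
            words.append(_FILLERS[k % len(_FILLERS)])
            k += 1
    assert (len(words) >= 10) == bool(active.get("WC", 0))
    order = list(words[:2]) + sorted(words[2:], key=lambda w: rng.random())
    return (" ".join(order)).capitalize() + "."


def generate_item_bank(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[ItemParameters], pd.DataFrame]:
    """Draw GRM item parameters, complexity profiles and item texts.

    Discriminations are lognormal around 1.5; thresholds are strictly
    increasing with a minimum gap.  Each item receives an integer complexity
    0-9 from the configured distribution, realized as a random subset of the
    ten binary indicators and (for the seven lexical/textual ones) an item
    text that codes back to exactly that subset.
    """
    rng = config.rng() if rng is None else rng
    params: list[ItemParameters] = []
    rows = []
    comp_p = np.asarray(config.complexity_distribution)
    lo, hi = config.categories_range
    for s, size in enumerate(config.scale_sizes):
        scale_id = f"S{s + 1:02d}"
        m_scale = int(rng.integers(lo, hi + 1))
        for j in range(size):
            item_id = f"{scale_id}I{j + 1}"
            # discriminations around 3 reproduce the tight, right-skewed
            # error-score distribution (median ~ .1) typical of established
            # rating scales; lower values inflate ordinary response noise
            # until it swamps the lapse signal in the top error decile
            a = float(rng.lognormal(np.log(3.0), 0.25))
            raw = np.sort(rng.normal(0.0, 1.2, m_scale - 1))
            b = raw.copy()
            for k in range(1, len(b)):
                b[k] = max(b[k], b[k - 1] + 0.25)
            b -= b.mean()
            params.append(ItemParameters(item_id, scale_id, m_scale, a, tuple(b)))

            comp = int(rng.choice(10, p=comp_p))
            on = rng.choice(10, size=comp, replace=False)
            indicators = {c: 0 for c in INDICATOR_COLUMNS}
            for idx in on:
                indicators[INDICATOR_COLUMNS[idx]] = 1
            text = _synthesize_text(indicators, rng)
            row = {"item_id": item_id, "scale_id": scale_id, "n_categories": m_scale,
                   "item_text": text, **indicators, "complexity": comp}
            rows.append(row)
    items = pd.DataFrame(rows)
    assert (items[INDICATOR_COLUMNS].sum(axis=1) == items["complexity"]).all()
    return params, items


def _exchangeable_waves(rng, n, n_waves, rho):
    """(n, n_waves) standard-normal draws with corr(w, w') = rho for w != w'."""
    common = rng.normal(size=(n, 1))
    unique = rng.normal(size=(n, n_waves))
    return np.sqrt(rho) * common + np.sqrt(1 - rho) * unique


def generate_persons(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> PersonSample:
    """Persons for a single wave: g ~ N(0,1), per-scale latents correlated
    with g at the configured level, and a person-level lapse offset."""
    return _generate_person_waves(config, config.rng() if rng is None else rng)[0]


def _generate_person_waves(config, rng) -> list[PersonSample]:
    n, S, W = config.n_persons, config.n_scales, config.n_waves
    rho_w = config.wave_retest_corr
    g = _exchangeable_waves(rng, n, W, rho_w)
    omega_std = _exchangeable_waves(rng, n, W, rho_w)
    rho = config.ability_theta_corr
    ids = [f"P{i + 1:05d}" for i in range(n)]
    scale_ids = [f"S{s + 1:02d}" for s in range(S)]
    out = []
    for w in range(W):
        eps = rng.normal(size=(n, S))
        thetas = rho * g[:, [w]] + np.sqrt(1 - rho**2) * eps
        persons = pd.DataFrame({
            "person_id": ids,
            "g": g[:, w],
            "lapse_offset": config.lapse_person_sd * omega_std[:, w],
        })
        out.append(PersonSample(persons, thetas, scale_ids))
    return out


def generate_responses(
    sample: PersonSample,
    item_params: list[ItemParameters],
    items: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    wave: int = 1,
) -> pd.DataFrame:
    """Contaminated GRM responses in long format.

    Returns columns person_id, wave, scale_id, item_id, response, lapse
    (the truth indicator; dropped by the CSV writer).  Missing responses are
    removed rows (rate = ``config.missing_rate``).
    """
    scale_pos = {sid: k for k, sid in enumerate(sample.scale_ids)}
    complexity = items.set_index("item_id")["complexity"]
    g = sample.g
    omega = sample.lapse_offset
    n = len(g)
    frames = []
    for item in item_params:
        if item.scale_id not in scale_pos:
            raise ValueError(f"item {item.item_id}: unknown scale {item.scale_id}")
        theta = sample.scale_thetas[:, scale_pos[item.scale_id]]
        pstar = cumulative_probabilities(theta, item)  # (n, m)
        u = rng.random(n)
        y = 1 + (u[:, None] < pstar[:, 1:]).sum(axis=1)
        c = float(complexity.loc[item.item_id])
        logit = (config.lapse_intercept + config.lapse_ability_slope * g
                 + config.lapse_complexity_slope * c
                 + config.lapse_interaction * g * c + omega)
        lapse = rng.random(n) < expit(logit)
        if lapse.any():
            m = item.n_categories
            if config.contamination == "uniform":
                y[lapse] = rng.integers(1, m + 1, size=int(lapse.sum()))
            else:  # extreme-response contamination
                y[lapse] = np.where(rng.random(int(lapse.sum())) < 0.5, 1, m)
        frames.append(pd.DataFrame({
            "person_id": sample.persons["person_id"],
            "wave": wave,
            "scale_id": item.scale_id,
            "item_id": item.item_id,
            "response": y,
            "lapse": lapse,
        }))
    out = pd.concat(frames, ignore_index=True)
    if config.missing_rate > 0:
        out = out[rng.random(len(out)) >= config.missing_rate].reset_index(drop=True)
    return out


def generate_cognitive_subtests(
    sample: PersonSample,
    config: SimulationConfig,
    rng: np.random.Generator,
    wave: int = 1,
) -> pd.DataFrame:
    """Four discretized subtests loading on g plus the 0-27 sum composite.

    The two recall subtests share an extra residual factor so that their
    partial correlation given g equals roughly ``recall_residual_corr``.
    """
    g = sample.g
    n = len(g)
    shared = rng.normal(size=n)
    cols = {"person_id": sample.persons["person_id"], "wave": wave}
    for name, mx, mean, sd, lam, recall in _SUBTESTS:
        c2 = config.recall_residual_corr * (1 - lam**2) if recall else 0.0
        resid = np.sqrt(max(1 - lam**2 - c2, 0.0))
        z = lam * g + np.sqrt(c2) * shared + resid * rng.normal(size=n)
        cols[name] = np.clip(np.round(mean + sd * z), 0, mx).astype(int)
    df = pd.DataFrame(cols)
    df["composite"] = df[[s[0] for s in _SUBTESTS]].sum(axis=1)
    assert df["composite"].between(0, 27).all()
    return df


@dataclass
class StudyData:
    """One synthetic study: item bank, persons, responses, cognition, truth."""

    config: SimulationConfig
    item_params: list
    items: pd.DataFrame
    person_waves: list
    responses: pd.DataFrame      # all waves, long, with truth lapse column
    cognition: pd.DataFrame      # all waves

    @property
    def persons(self) -> pd.DataFrame:
        return self.person_waves[0].persons

    @property
    def quaid_flags(self) -> pd.DataFrame:
        return self.items[["item_id", "UTT", "VRT", "VNP"]].copy()

    def truth(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        cfg["complexity_distribution"] = list(cfg["complexity_distribution"])
        cfg["scale_sizes"] = list(cfg["scale_sizes"])
        cfg["categories_range"] = list(cfg["categories_range"])
        return {
            "config": cfg,
            "item_parameters": {
                p.item_id: {"scale_id": p.scale_id, "m": p.n_categories,
                            "a": p.discrimination, "b": list(p.thresholds)}
                for p in self.item_params
            },
            "lapse_rate": float(self.responses["lapse"].mean()),
        }

    def write(self, outdir: str | Path) -> dict:
        """Write responses.csv, items.csv, cognition.csv, quaid_flags.csv and
        truth.json; returns a row-count manifest fragment."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        resp = self.responses.drop(columns=["lapse"])
        resp.to_csv(outdir / "responses.csv", index=False)
        self.items.to_csv(outdir / "items.csv", index=False)
        self.cognition.to_csv(outdir / "cognition.csv", index=False)
        self.quaid_flags.to_csv(outdir / "quaid_flags.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth(), indent=1))
        return {"responses": len(resp), "items": len(self.items),
                "cognition": len(self.cognition)}


def generate_panel(config: SimulationConfig) -> StudyData:
    """Full multi-wave study from one seeded generator pass."""
    rng = config.rng()
    item_params, items = generate_item_bank(config, rng)
    waves = _generate_person_waves(config, rng)
    resp_frames, cog_frames = [], []
    for w, sample in enumerate(waves, start=1):
        resp_frames.append(generate_responses(sample, item_params, items, config, rng, wave=w))
        cog_frames.append(generate_cognitive_subtests(sample, config, rng, wave=w))
    return StudyData(
        config=config,
        item_params=item_params,
        items=items,
        person_waves=waves,
        responses=pd.concat(resp_frames, ignore_index=True),
        cognition=pd.concat(cog_frames, ignore_index=True),
    )


def simulate_study(config: SimulationConfig | None = None, **overrides) -> StudyData:
    """Convenience wrapper: build a config (defaults plus overrides) and
    generate the study."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    return generate_panel(config)
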