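"""Synthetic spontaneous-report generator with known reporting-odds truth.

Emulates the structure of FAERS quarterly extracts — per-case drug lists
(with polypharmacy and exact duplicate submissions), per-case preferred-term
lists, sex/age/route demographics and therapy start dates — under a
generative model simple enough that every downstream estimate has a closed
form:

* each case receives one drug (uniform over the catalog), or exactly two
  distinct drugs with probability ``polypharmacy_prob``;
* each preferred term ``t`` is included independently with probability
  ``odds_t * m / (1 + odds_t * m)`` where ``odds_t`` is the baseline odds
  ``p_t / (1 - p_t)`` and ``m`` is the product of the configured odds
  multipliers theta(drug, t) over the case's drugs;
* sex is Bernoulli(``p_female``); age is Normal(mean, sd) truncated to
  [0, 110] years; routes are drawn per (case, drug) from the drug's route
  distribution; therapy start dates are uniform over a window;
* with probability ``duplicate_prob`` a case's reaction rows are emitted
  twice — each of its integrated rows then occurs exactly twice —
  exercising deduplication downstream.

Independence of terms within a case is a deliberate simplification (no
syndrome co-reporting); it is exactly what makes the reporting odds ratio
identifiable from the configuration — see :class:`SimTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from thrombosignal.io import normalize_name
from thrombosignal.signals import ContingencyTable

__all__ = [
    "DrugSpec",
    "PtSpec",
    "SimConfig",
    "SimTables",
    "SimTruth",
    "generate",
    "expected_contingency",
    "write_tables",
]

#: truncation bounds for simulated ages, years
AGE_BOUNDS = (0.0, 110.0)


@dataclass(frozen=True)
class DrugSpec:
    """One catalog drug: name, optional structure, class and route mix."""

    name: str
    smiles: str | None = None
    drug_class: str = "unclassified"
    routes: tuple[tuple[str, float], ...] = (("ORAL", 1.0),)


@dataclass(frozen=True)
class PtSpec:
    """One catalog preferred term with its baseline reporting probability."""

    pt: str
    baseline: float
    scope: str = "none"  # arterial / venous / mixed / none


@dataclass
class SimConfig:
    """Full configuration of the generative model.

    ``effects`` maps (drug_name, pt) to the reporting-odds multiplier
    theta >= 0; pairs not listed have theta = 1 (no association).
    """

    n_cases: int
    drugs: list[DrugSpec]
    pts: list[PtSpec]
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    polypharmacy_prob: float = 0.15
    duplicate_prob: float = 0.05
    p_female: float = 0.6
    age_mean: float = 55.0
    age_sd: float = 18.0
    start_window: tuple[str, str] = ("2004-01-01", "2024-09-30")
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if len(self.drugs) < 1 or len(self.pts) < 1:
            raise ValueError("drug and PT catalogs must be nonempty")
        names = [normalize_name(d.name) for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names in catalog")
        pts = [normalize_name(p.pt) for p in self.pts]
        if len(set(pts)) != len(pts):
            raise ValueError("duplicate preferred terms in catalog")
        for p in self.pts:
            if not 0.0 < p.baseline < 1.0:
                raise ValueError(
                    f"baseline probability for {p.pt!r} must be in (0,1)")
        for (d, t), theta in self.effects.items():
            if normalize_name(d) not in names:
                raise ValueError(f"effect references unknown drug {d!r}")
            if normalize_name(t) not in pts:
                raise ValueError(f"effect references unknown PT {t!r}")
            if not np.isfinite(theta) or theta < 0:
                raise ValueError(f"theta for ({d!r}, {t!r}) must be finite "
                                 "and non-negative")
        for prob, label in [(self.polypharmacy_prob, "polypharmacy_prob"),
                            (self.duplicate_prob, "duplicate_prob"),
                            (self.p_female, "p_female")]:
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"{label} must be in [0, 1]")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        if len(self.drugs) == 1 and self.polypharmacy_prob > 0:
            raise ValueError("polypharmacy requires >= 2 catalog drugs")

    # -- derived arrays -----------------------------------------------------

    def drug_names(self) -> list[str]:
        return [normalize_name(d.name) for d in self.drugs]

    def pt_names(self) -> list[str]:
        return [normalize_name(p.pt) for p in self.pts]

    def theta_matrix(self) -> np.ndarray:
        """(n_drugs, n_pts) array of odds multipliers, default 1."""
        names = {n: i for i, n in enumerate(self.drug_names())}
        pts = {p: j for j, p in enumerate(self.pt_names())}
        theta = np.ones((len(names), len(pts)))
        for (d, t), v in self.effects.items():
            theta[names[normalize_name(d)], pts[normalize_name(t)]] = v
        return theta

    def baseline_odds(self) -> np.ndarray:
        p = np.array([s.baseline for s in self.pts])
        return p / (1.0 - p)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["drugs"] = [
            DrugSpec(name=s["name"], smiles=s.get("smiles"),
                     drug_class=s.get("drug_class", "unclassified"),
                     routes=tuple((r, w) for r, w in
                                  s.get("routes", {"ORAL": 1.0}).items()))
            for s in d["drugs"]]
        d["pts"] = [PtSpec(pt=s["pt"], baseline=float(s["baseline"]),
                           scope=s.get("scope", "none")) for s in d["pts"]]
        d["effects"] = {(e["drug"], e["pt"]): float(e["theta"])
                        for e in d.get("effects", [])}
        if "start_window" in d:
            d["start_window"] = tuple(d["start_window"])
        return cls(**d)


@dataclass
class SimTables:
    """The four generated record tables, in canonical column form."""

    drug: pd.DataFrame
    reac: pd.DataFrame
    demo: pd.DataFrame
    ther: pd.DataFrame


class SimTruth:
    """Closed-form expectations implied by a :class:`SimConfig`.

    Expectations refer to the deduplicated, monotherapy-filtered integrated
    table: a monotherapy case with drug ``d`` occurs with probability
    ``(1 - polypharmacy_prob) / n_drugs`` and contributes one row per
    included term, so the expected number of (d, t) rows is
    ``n_cases * P(mono, d) * q(d, t)`` with
    ``q = odds_t * theta(d, t) / (1 + odds_t * theta(d, t))``.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        self._q = None

    def _q_matrix(self) -> np.ndarray:
        if self._q is None:
            o = self.config.baseline_odds()[None, :]
            ot = o * self.config.theta_matrix()
            self._q = ot / (1.0 + ot)
        return self._q

    def expected_rows(self) -> pd.DataFrame:
        """Expected deduplicated monotherapy row counts, drugs x PTs."""
        cfg = self.config
        p_mono = (1.0 - cfg.polypharmacy_prob) / len(cfg.drugs)
        counts = cfg.n_cases * p_mono * self._q_matrix()
        return pd.DataFrame(counts, index=cfg.drug_names(),
                            columns=cfg.pt_names())

    def expected_contingency(self, drug: str, pt_set) -> ContingencyTable:
        """Expected 2x2 cells for ``drug`` against the term set ``pt_set``.

        Raises ``KeyError`` for a drug or term absent from the catalog.
        """
        cfg = self.config
        drug = normalize_name(drug)
        wanted = {normalize_name(t) for t in pt_set}
        unknown = wanted - set(cfg.pt_names())
        if unknown:
            raise KeyError(f"unknown preferred term(s): {sorted(unknown)}")
        exp = self.expected_rows()
        if drug not in exp.index:
            raise KeyError(f"unknown drug {drug!r}")
        in_set = exp.columns.isin(wanted)
        a = float(exp.loc[drug, in_set].sum())
        b = float(exp.loc[drug, ~in_set].sum())
        others = exp.drop(index=drug)
        c = float(others.loc[:, in_set].to_numpy().sum())
        d = float(others.loc[:, ~in_set].to_numpy().sum())
        return ContingencyTable(a, b, c, d)

    def expected_ror(self, drug: str, pt_set) -> float:
        t = self.expected_contingency(drug, pt_set)
        return (t.a * t.d) / (t.b * t.c)


def generate(config: SimConfig) -> tuple[SimTables, SimTruth]:
    """Draw one synthetic report collection; reproducible for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    n_drugs = len(config.drugs)
    drug_names = np.array(config.drug_names())
    pt_names = np.array(config.pt_names())

    case_ids = np.char.add("C", np.arange(1, n + 1).astype(str))

    poly = rng.random(n) < config.polypharmacy_prob
    d1 = rng.integers(0, n_drugs, n)
    if n_drugs > 1:
        d2 = (d1 + 1 + rng.integers(0, n_drugs - 1, n)) % n_drugs
    else:
        d2 = d1.copy()

    # per-case inclusion probability for every PT
    theta = config.theta_matrix()
    mult = theta[d1].copy()
    if poly.any():
        mult[poly] *= theta[d2[poly]]
    odds = config.baseline_odds()[None, :] * mult
    q = odds / (1.0 + odds)
    inc = rng.random((n, len(config.pts))) < q

    # DRUG rows: primary suspect for everyone, secondary for polypharmacy
    route_choices = []
    for spec in config.drugs:
        labels = np.array([r for r, _ in spec.routes])
        w = np.array([w for _, w in spec.routes], dtype=float)
        route_choices.append((labels, w / w.sum()))

    def _routes(idx: np.ndarray) -> np.ndarray:
        out = np.empty(len(idx), dtype=object)
        for k in range(n_drugs):
            mask = idx == k
            if mask.any():
                labels, w = route_choices[k]
                out[mask] = rng.choice(labels, size=int(mask.sum()), p=w)
        return out

    drug_case = np.concatenate([case_ids, case_ids[poly]])
    drug_idx = np.concatenate([d1, d2[poly]])
    role = np.concatenate([np.full(n, "PS"), np.full(int(poly.sum()), "SS")])
    drug_df = pd.DataFrame({
        "case_id": drug_case,
        "drug_name": drug_names[drug_idx],
        "role_code": role,
        "route": _routes(drug_idx),
    })

    ci, ti = np.nonzero(inc)
    reac_df = pd.DataFrame({"case_id": case_ids[ci], "pt": pt_names[ti]})

    # duplicate submissions: the case's reaction rows are emitted twice, so
    # each of its integrated (case, drug, pt) rows appears exactly twice
    # (duplicating DRUG rows as well would square the join multiplicity)
    dup = rng.random(n) < config.duplicate_prob
    if dup.any():
        dup_cases = set(case_ids[dup])
        reac_df = pd.concat(
            [reac_df, reac_df[reac_df["case_id"].isin(dup_cases)]],
            ignore_index=True)

    sex = np.where(rng.random(n) < config.p_female, "F", "M")
    lo, hi = AGE_BOUNDS
    a_std = (lo - config.age_mean) / config.age_sd
    b_std = (hi - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a_std, b_std, loc=config.age_mean,
                        scale=config.age_sd, size=n, random_state=rng)
    demo_df = pd.DataFrame({"case_id": case_ids, "sex": sex,
                            "age_years": np.round(age, 1)})

    t0 = pd.Timestamp(config.start_window[0])
    t1 = pd.Timestamp(config.start_window[1])
    span = (t1 - t0).days
    offs = rng.integers(0, span + 1, len(drug_case))
    start = (t0 + pd.to_timedelta(offs, unit="D")).strftime("%Y%m%d")
    ther_df = pd.DataFrame({"case_id": drug_case,
                            "drug_name": drug_names[drug_idx],
                            "start_date": start})

    return SimTables(drug_df, reac_df, demo_df, ther_df), SimTruth(config)


def expected_contingency(config: SimConfig, drug: str, pt_set) -> ContingencyTable:
    """Module-level convenience wrapper over :meth:`SimTruth.expected_contingency`."""
    return SimTruth(config).expected_contingency(drug, pt_set)


def write_tables(tables: SimTables, out_dir, sep: str = "$") -> dict[str, str]:
    """Write the four tables in the FAERS ASCII dialect :mod:`thrombosignal.io` reads."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mapping = {
        "DRUG": (tables.drug, {"case_id": "primaryid", "drug_name": "drugname",
                               "role_code": "role_cod", "route": "route"}),
        "REAC": (tables.reac, {"case_id": "primaryid", "pt": "pt"}),
        "DEMO": (tables.demo, {"case_id": "primaryid", "sex": "sex",
                               "age_years": "age"}),
        "THER": (tables.ther, {"case_id": "primaryid", "drug_name": "drugname",
                               "start_date": "start_dt"}),
    }
    paths = {}
    for name, (df, cols) in mapping.items():
        path = out / f"{name}.txt"
        d = df[list(cols)].rename(columns=cols)
        if name == "DEMO":
            d = d.assign(age_cod="YR")
        d.to_csv(path, sep=sep, index=False)
        paths[name.lower()] = str(path)
    return paths


# ---------------------------------------------------------------------------
# Canned study conditions used by the calibration checks and the CLI demo.

def null_calibration_config(n_cases: int = 20_000, n_drugs: int = 100,
                            seed: int = 0) -> SimConfig:
    """No-association condition: theta = 1 everywhere.

    100 catalog drugs, six thrombosis-type terms at ~2% baseline and
    fourteen unrelated terms at ~5%; used to check the type-I rate of the
    signal flag.
    """
    thrombo = ["DEEP VEIN THROMBOSIS", "PULMONARY EMBOLISM",
               "MYOCARDIAL INFARCTION", "CEREBRAL INFARCTION",
               "THROMBOSIS", "EMBOLISM VENOUS"]
    scopes = ["venous", "venous", "arterial", "arterial", "mixed", "venous"]
    other = [f"OTHER EVENT {i:02d}" for i in range(14)]
    pts = ([PtSpec(t, 0.02, s) for t, s in zip(thrombo, scopes)]
           + [PtSpec(t, 0.05) for t in other])
    drugs = [DrugSpec(f"DRUG{i:03d}") for i in range(n_drugs)]
    return SimConfig(n_cases=n_cases, drugs=drugs, pts=pts, effects={},
                     polypharmacy_prob=0.15, duplicate_prob=0.05, seed=seed)


def demo_study_config(n_cases: int = 50_000, seed: int = 0) -> SimConfig:
    """A steroid-vs-thrombosis study in miniature.

    Ten steroids (with structures, drawn from the packaged scaffold
    fixture) and ten structurally unrelated drugs; five venous, five
    arterial and two mixed-vessel thrombosis terms plus ten unrelated
    events.  Sex-hormone preparations carry elevated reporting odds on the
    venous terms, cardiovascular/mineralocorticoid-axis steroids on the
    arterial terms, and glucocorticoids a milder lift on both — the
    qualitative contrast the PCA/cluster stage is meant to surface.
    """
    from thrombosignal.cohort import scaffold_fixture

    fixture = scaffold_fixture()
    drugs = [DrugSpec(r["drug_name"], smiles=r["smiles"])
             for _, r in fixture.iterrows()]
    venous = ["DEEP VEIN THROMBOSIS", "PULMONARY EMBOLISM",
              "SUPERFICIAL VEIN THROMBOSIS", "VENOUS THROMBOSIS",
              "THROMBOPHLEBITIS"]
    arterial = ["MYOCARDIAL INFARCTION", "CEREBRAL INFARCTION",
                "ISCHAEMIC STROKE", "ARTERIAL OCCLUSIVE DISEASE",
                "TRANSIENT ISCHAEMIC ATTACK"]
    mixed = ["THROMBOSIS", "EMBOLISM"]
    pts = ([PtSpec(t, 0.02, "venous") for t in venous]
           + [PtSpec(t, 0.02, "arterial") for t in arterial]
           + [PtSpec(t, 0.02, "mixed") for t in mixed]
           + [PtSpec(f"OTHER EVENT {i:02d}", 0.04) for i in range(10)])
    # sex-hormone steroids lean venous, cardiovascular/mineralocorticoid-
    # axis steroids lean arterial, glucocorticoids lift both mildly; the
    # venous/arterial contrast is the dominant latent axis of the design
    effects: dict[tuple[str, str], float] = {}
    for d in ["ESTRADIOL", "ETHINYLESTRADIOL", "PROGESTERONE"]:
        for t in venous:
            effects[(d, t)] = 5.0
        for t in arterial:
            effects[(d, t)] = 1.6
        for t in mixed:
            effects[(d, t)] = 2.5
    for d in ["TESTOSTERONE", "DIGOXIGENIN", "SPIRONOLACTONE"]:
        for t in arterial:
            effects[(d, t)] = 5.0
        for t in venous:
            effects[(d, t)] = 1.6
        for t in mixed:
            effects[(d, t)] = 2.5
    for d in ["HYDROCORTISONE", "PREDNISOLONE", "DEXAMETHASONE"]:
        for t in venous + arterial + mixed:
            effects[(d, t)] = 2.0
    return SimConfig(n_cases=n_cases, drugs=drugs, pts=pts, effects=effects,
                     polypharmacy_prob=0.15, duplicate_prob=0.05, seed=seed)


def effect_recovery_config(theta: float = 3.0, n_cases: int = 50_000,
                           seed: int = 0) -> SimConfig:
    """Single planted association: theta(DRUG000, DEEP VEIN THROMBOSIS).

    20 catalog drugs and a 1% baseline target term, sized so the
    monotherapy arm of the target drug has ~2000 cases.
    """
    pts = ([PtSpec("DEEP VEIN THROMBOSIS", 0.01, "venous")]
           + [PtSpec(f"OTHER EVENT {i:02d}", 0.05) for i in range(14)])
    drugs = [DrugSpec(f"DRUG{i:03d}") for i in range(20)]
    effects = {("DRUG000", "DEEP VEIN THROMBOSIS"): theta}
    return SimConfig(n_cases=n_cases, drugs=drugs, pts=pts, effects=effects,
                     polypharmacy_prob=0.2, duplicate_prob=0.05, seed=seed)
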