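"""Synthetic pelvic-mass cohorts with known operating characteristics.

The generator draws independent women with the marginal structure of a
surgical pelvic-mass population seen in a mixed cancer-centre / general-
hospital setting: ~21% malignancy prevalence (borderline tumours counted
as malignant and generated as a sub-label with attenuated feature and
marker separation), ~69% premenopausal, a higher malignancy rate at the
cancer centre, and an inconclusive-IOTA rate in the 20-30% range.

Model structure (deliberately simple so every strategy's true operating
point has a closed form):

* truth class (benign / borderline / invasive-malignant) given site;
* IOTA colour score from a class-conditional 4-category distribution,
  with the two flow features derived from it (score 1 = no flow,
  score 4 = very strong flow), so the flow flags are exclusive by
  construction;
* the remaining feature flags Bernoulli, conditionally independent given
  class; ascites is drawn once and enters both the M-feature set and the
  RMI feature set;
* CA125 and HE4 log-normal given (class, menopausal status), independent
  of the feature flags;
* the expert call is a noisy copy of the truth with configurable
  sensitivity/specificity.

These independence assumptions are a modelling simplification, not a
claim about real tumours; they are what makes
:func:`analytic_operating_points` exact, which in turn is what lets the
full pipeline be tested by parameter recovery.

Reproducibility contract: one ``numpy`` Generator per cohort, seeded
explicitly; draws are made field by field in a fixed, documented order
(site, class, borderline, ovarian, menopause, stage, colour, B-flags,
M-flags, RMI flags, CA125, HE4, HE4-missingness, expert, age), so adding
a new field later appends draws without shifting existing ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .cohort import Cohort, PatientRecord, UltrasoundExam
from .scores import RMI_MENOPAUSAL_SCORE, ROMA_COEFFICIENTS, Thresholds

TRUTH_CLASSES = ("benign", "borderline", "malignant")
_MENOPAUSE = ("pre", "post")


@dataclass(frozen=True)
class ClassFeatureModel:
    """Class-conditional ultrasound feature probabilities.

    ``colour_dist``: probabilities of IOTA colour score 1..4.
    ``b_flags``: unilocular, solid<7mm, acoustic shadows, smooth
    multilocular <100mm.  ``m_flags``: irregular solid, ascites, >=4
    papillary structures, irregular multilocular solid >=100mm.
    ``rmi_flags``: multilocular, solid areas, metastases, bilateral
    (ascites is shared with ``m_flags[1]``).
    """

    colour_dist: tuple[float, float, float, float]
    b_flags: tuple[float, float, float, float]
    m_flags: tuple[float, float, float, float]
    rmi_flags: tuple[float, float, float, float]


@dataclass(frozen=True)
class MarkerModel:
    """Log-normal location/scale of CA125 (U/mL) and HE4 (pmol/L)."""

    ca125_mu: float
    ca125_sigma: float
    he4_mu: float
    he4_sigma: float


@dataclass(frozen=True)
class GeneratorParams:
    n: int = 690
    prevalence: float = 0.206  # P(truth malignant, borderline included)
    borderline_frac: float = 36.0 / 179.0
    premenopausal_frac: float = 478.0 / 690.0
    site_mix: float = 341.0 / 690.0  # P(cancer_centre)
    # site-specific malignancy relative risks; must mix to 1 under site_mix
    site_rr: tuple[float, float] = (
        (112.0 * 690.0) / (341.0 * 142.0),
        (30.0 * 690.0) / (349.0 * 142.0),
    )
    features: dict[str, ClassFeatureModel] = field(default_factory=lambda: dict(_DEFAULT_FEATURES))
    markers: dict[str, dict[str, MarkerModel]] = field(default_factory=lambda: {
        cls: dict(v) for cls, v in _DEFAULT_MARKERS.items()
    })
    expert_sens: float = 0.81
    expert_spec: float = 0.717
    expert_coverage: str = "inconclusive"  # or "all"
    stage_dist: tuple[float, float, float, float, float] = (
        51 / 114, 15 / 114, 25 / 114, 12 / 114, 11 / 114,
    )
    nonovarian_frac: float = 0.075
    he4_missing_frac: float = 0.0
    seed: int = 0

    @property
    def site_prevalence(self) -> tuple[float, float]:
        """Implied (cancer_centre, general_unit) malignancy probabilities."""
        return (self.prevalence * self.site_rr[0], self.prevalence * self.site_rr[1])


#: Defaults calibrated analytically so IOTA on its conclusive stratum runs
#: near 81% sensitivity / 97% specificity, ROMA alone near the low-80s on
#: both axes, the inconclusive rate falls in the 20-30% band, and
#: borderline tumours are substantially harder to call than invasive ones.
_DEFAULT_FEATURES: dict[str, ClassFeatureModel] = {
    "benign": ClassFeatureModel(
        colour_dist=(0.44, 0.36, 0.18, 0.02),
        b_flags=(0.45, 0.06, 0.15, 0.25),
        m_flags=(0.035, 0.013, 0.010, 0.008),
        rmi_flags=(0.30, 0.12, 0.004, 0.10),
    ),
    "borderline": ClassFeatureModel(
        colour_dist=(0.15, 0.30, 0.40, 0.15),
        b_flags=(0.10, 0.08, 0.05, 0.12),
        m_flags=(0.18, 0.08, 0.08, 0.06),
        rmi_flags=(0.45, 0.40, 0.02, 0.20),
    ),
    "malignant": ClassFeatureModel(
        colour_dist=(0.06, 0.18, 0.40, 0.36),
        b_flags=(0.10, 0.08, 0.06, 0.06),
        m_flags=(0.42, 0.155, 0.15, 0.14),
        rmi_flags=(0.45, 0.75, 0.25, 0.30),
    ),
}

_DEFAULT_MARKERS: dict[str, dict[str, MarkerModel]] = {
    "benign": {
        "pre": MarkerModel(ca125_mu=3.60, ca125_sigma=1.00, he4_mu=3.66, he4_sigma=0.24),
        "post": MarkerModel(ca125_mu=2.95, ca125_sigma=0.85, he4_mu=4.05, he4_sigma=0.25),
    },
    "borderline": {
        "pre": MarkerModel(ca125_mu=3.90, ca125_sigma=1.00, he4_mu=3.90, he4_sigma=0.40),
        "post": MarkerModel(ca125_mu=3.70, ca125_sigma=1.00, he4_mu=4.30, he4_sigma=0.50),
    },
    "malignant": {
        "pre": MarkerModel(ca125_mu=5.50, ca125_sigma=1.50, he4_mu=5.00, he4_sigma=1.20),
        "post": MarkerModel(ca125_mu=5.20, ca125_sigma=1.50, he4_mu=4.90, he4_sigma=0.90),
    },
}


class ParameterError(ValueError):
    pass


def validate_params(params: GeneratorParams) -> None:
    """Raise :class:`ParameterError` on any invariant violation."""
    def check_prob(name: str, p: float) -> None:
        if not 0 <= p <= 1:
            raise ParameterError(f"{name}: probability must lie in [0, 1], got {p}")

    check_prob("prevalence", params.prevalence)
    check_prob("borderline_frac", params.borderline_frac)
    check_prob("premenopausal_frac", params.premenopausal_frac)
    check_prob("site_mix", params.site_mix)
    check_prob("expert_sens", params.expert_sens)
    check_prob("expert_spec", params.expert_spec)
    check_prob("nonovarian_frac", params.nonovarian_frac)
    check_prob("he4_missing_frac", params.he4_missing_frac)
    if params.n < 0:
        raise ParameterError("n: must be non-negative")
    if params.expert_coverage not in ("inconclusive", "all"):
        raise ParameterError("expert_coverage: must be 'inconclusive' or 'all'")
    mix = params.site_mix * params.site_rr[0] + (1 - params.site_mix) * params.site_rr[1]
    if abs(mix - 1.0) > 1e-9:
        raise ParameterError(
            f"site_rr: relative risks must mix to 1 under site_mix, got {mix:.6f}"
        )
    for p_site in params.site_prevalence:
        check_prob("site prevalence (prevalence * site_rr)", p_site)
    if abs(sum(params.stage_dist) - 1.0) > 1e-9:
        raise ParameterError("stage_dist: must sum to 1")
    for cls in TRUTH_CLASSES:
        fm = params.features[cls]
        if abs(sum(fm.colour_dist) - 1.0) > 1e-9:
            raise ParameterError(f"features[{cls}].colour_dist: must sum to 1")
        for group in ("colour_dist", "b_flags", "m_flags", "rmi_flags"):
            for p in getattr(fm, group):
                check_prob(f"features[{cls}].{group}", p)
        for meno in _MENOPAUSE:
            mm = params.markers[cls][meno]
            if mm.ca125_sigma < 0 or mm.he4_sigma < 0:
                raise ParameterError(f"markers[{cls}][{meno}]: sigma must be >= 0")


def default_params(n: int = 690, seed: int = 0, **overrides) -> GeneratorParams:
    """The study-condition defaults (see module docstring), validated."""
    params = GeneratorParams(n=n, seed=seed, **overrides)
    validate_params(params)
    return params


# ---------------------------------------------------------------------------
# serialization

def params_to_dict(params: GeneratorParams) -> dict:
    return asdict(params)


def params_from_dict(data: dict) -> GeneratorParams:
    data = dict(data)
    if "features" in data:
        data["features"] = {
            cls: ClassFeatureModel(**{k: tuple(v) for k, v in fm.items()})
            if not isinstance(fm, ClassFeatureModel) else fm
            for cls, fm in data["features"].items()
        }
    if "markers" in data:
        data["markers"] = {
            cls: {
                meno: MarkerModel(**mm) if not isinstance(mm, MarkerModel) else mm
                for meno, mm in per_meno.items()
            }
            for cls, per_meno in data["markers"].items()
        }
    for key in ("site_rr", "stage_dist"):
        if key in data:
            data[key] = tuple(data[key])
    params = GeneratorParams(**data)
    validate_params(params)
    return params


def save_params(params: GeneratorParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=False))


def load_params(path: str | Path) -> GeneratorParams:
    return params_from_dict(yaml.safe_load(Path(path).read_text()))


def params_digest(params: GeneratorParams) -> str:
    payload = json.dumps(params_to_dict(params), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# generation

def generate_cohort(params: GeneratorParams) -> Cohort:
    """Draw ``params.n`` independent records; bit-stable under fixed seed."""
    validate_params(params)
    n = params.n
    rng = np.random.default_rng(params.seed)

    # field-order contract: the draw sequence below is append-only
    site_cc = rng.random(n) < params.site_mix
    p_mal = np.where(site_cc, params.site_prevalence[0], params.site_prevalence[1])
    malignant = rng.random(n) < p_mal
    borderline = malignant & (rng.random(n) < params.borderline_frac)
    ovarian = rng.random(n) >= params.nonovarian_frac
    pre = rng.random(n) < params.premenopausal_frac

    cls = np.where(~malignant, "benign", np.where(borderline, "borderline", "malignant"))

    stage_u = rng.random(n)
    stage_cum = np.cumsum(params.stage_dist)
    stage_idx = np.searchsorted(stage_cum, stage_u, side="right").clip(0, 4)
    stage_labels = np.array(["I", "II", "III", "IV", "unstaged"])

    def per_class(getter) -> np.ndarray:
        values = {c: getter(params.features[c]) for c in TRUTH_CLASSES}
        out = np.empty(n, dtype=float)
        for c in TRUTH_CLASSES:
            out[cls == c] = values[c]
        return out

    colour_u = rng.random(n)
    colour = np.empty(n, dtype=int)
    for c in TRUTH_CLASSES:
        cum = np.cumsum(params.features[c].colour_dist)
        mask = cls == c
        colour[mask] = 1 + np.searchsorted(cum, colour_u[mask], side="right").clip(0, 3)

    b_flags = [rng.random(n) < per_class(lambda fm, i=i: fm.b_flags[i]) for i in range(4)]
    m_flags = [rng.random(n) < per_class(lambda fm, i=i: fm.m_flags[i]) for i in range(4)]
    r_flags = [rng.random(n) < per_class(lambda fm, i=i: fm.rmi_flags[i]) for i in range(4)]

    def marker_params(attr_mu: str, attr_sigma: str) -> tuple[np.ndarray, np.ndarray]:
        mu = np.empty(n)
        sigma = np.empty(n)
        for c in TRUTH_CLASSES:
            for meno, meno_mask in (("pre", pre), ("post", ~pre)):
                mask = (cls == c) & meno_mask
                mm = params.markers[c][meno]
                mu[mask] = getattr(mm, attr_mu)
                sigma[mask] = getattr(mm, attr_sigma)
        return mu, sigma

    ca_mu, ca_sigma = marker_params("ca125_mu", "ca125_sigma")
    ca125 = np.exp(ca_mu + ca_sigma * rng.standard_normal(n))
    he4_mu, he4_sigma = marker_params("he4_mu", "he4_sigma")
    he4 = np.exp(he4_mu + he4_sigma * rng.standard_normal(n))
    he4_missing = rng.random(n) < params.he4_missing_frac

    expert_u = rng.random(n)
    expert_correct = np.where(malignant, expert_u < params.expert_sens, expert_u < params.expert_spec)
    # correct -> truth label, incorrect -> the other label
    expert_label = np.where(
        expert_correct, np.where(malignant, "malignant", "benign"),
        np.where(malignant, "benign", "malignant"),
    )

    age = np.where(
        pre,
        np.clip(rng.normal(41.0, 8.0, n), 18, 55),
        np.clip(rng.normal(58.0, 7.0, n), 45, 89),
    )

    # IOTA conclusiveness (for expert coverage) from the drawn flags
    n_b = sum(np.asarray(f, dtype=int) for f in b_flags) + (colour == 1)
    n_m = sum(np.asarray(f, dtype=int) for f in m_flags) + (colour == 4)
    inconclusive = ((n_b == 0) & (n_m == 0)) | ((n_b >= 1) & (n_m >= 1))

    records: list[PatientRecord] = []
    for i in range(n):
        exam = UltrasoundExam(
            b_unilocular=bool(b_flags[0][i]),
            b_solid_lt7mm=bool(b_flags[1][i]),
            b_acoustic_shadows=bool(b_flags[2][i]),
            b_smooth_multiloc_lt100=bool(b_flags[3][i]),
            b_no_flow=bool(colour[i] == 1),
            m_irregular_solid=bool(m_flags[0][i]),
            m_ascites=bool(m_flags[1][i]),
            m_papillary_ge4=bool(m_flags[2][i]),
            m_irregular_multiloc_solid_ge100=bool(m_flags[3][i]),
            m_strong_flow=bool(colour[i] == 4),
            colour_score=int(colour[i]),
            rmi_multilocular=bool(r_flags[0][i]),
            rmi_solid_areas=bool(r_flags[1][i]),
            rmi_metastases=bool(r_flags[2][i]),
            rmi_ascites=bool(m_flags[1][i]),
            rmi_bilateral=bool(r_flags[3][i]),
        )
        expert: str | None = str(expert_label[i])
        if params.expert_coverage == "inconclusive" and not inconclusive[i]:
            expert = None
        figo: str | None = None
        if cls[i] == "malignant":
            figo = str(stage_labels[stage_idx[i]])
        records.append(
            PatientRecord(
                patient_id=f"S{params.seed}-{i:06d}",
                age=round(float(age[i]), 1),
                menopausal="pre" if pre[i] else "post",
                ca125=round(float(ca125[i]), 2),
                he4=None if he4_missing[i] else round(float(he4[i]), 2),
                exam=exam,
                expert_call=expert,
                histology=str(cls[i]),
                ovarian=bool(ovarian[i]),
                site="cancer_centre" if site_cc[i] else "general_unit",
                figo_stage=figo,
            )
        )
    return Cohort(records=records, provenance=f"generated(seed={params.seed},params={params_digest(params)})")


# ---------------------------------------------------------------------------
# analytic operating points

def _feature_distribution(fm: ClassFeatureModel) -> dict:
    """Exact joint of (IOTA call, RMI ultrasound score) for one class.

    Enumerates colour x B-flag x M-flag patterns (the ascites flag couples
    the M-set to the RMI count, so the joint is computed, not a product),
    with the four remaining RMI flags folded in via their count
    distribution.
    """
    flag_combos = list(product((0, 1), repeat=4))

    def combo_probs(probs: tuple[float, ...]) -> list[float]:
        out = []
        for combo in flag_combos:
            p = 1.0
            for bit, q in zip(combo, probs):
                p *= q if bit else (1 - q)
            out.append(p)
        return out

    b_probs = combo_probs(fm.b_flags)
    m_probs = combo_probs(fm.m_flags)
    # count distribution of the four non-ascites RMI flags
    r_count = np.zeros(5)
    for combo, p in zip(flag_combos, combo_probs(fm.rmi_flags)):
        r_count[sum(combo)] += p

    def u_of(count: int) -> float:
        return 0.0 if count == 0 else (1.0 if count == 1 else 3.0)

    p_call = {"malignant": 0.0, "benign": 0.0, "inconclusive": 0.0}
    p_u: dict[float, float] = {0.0: 0.0, 1.0: 0.0, 3.0: 0.0}
    p_inc_u: dict[float, float] = {0.0: 0.0, 1.0: 0.0, 3.0: 0.0}
    for ci, pc in enumerate(fm.colour_dist):
        score = ci + 1
        for bc, pb in zip(flag_combos, b_probs):
            n_b = sum(bc) + (score == 1)
            for mc, pm in zip(flag_combos, m_probs):
                n_m = sum(mc) + (score == 4)
                ascites = mc[1]
                base = pc * pb * pm
                if base == 0.0:
                    continue
                if n_m >= 1 and n_b == 0:
                    call = "malignant"
                elif n_b >= 1 and n_m == 0:
                    call = "benign"
                else:
                    call = "inconclusive"
                p_call[call] += base
                for k in range(5):
                    pk = r_count[k]
                    if pk == 0.0:
                        continue
                    u = u_of(k + ascites)
                    p_u[u] += base * pk
                    if call == "inconclusive":
                        p_inc_u[u] += base * pk
    return {"call": p_call, "u": p_u, "inc_u": p_inc_u}


def _normal_tail(threshold: float, mu: float, sigma: float) -> float:
    if sigma == 0.0:
        return 1.0 if mu >= threshold else 0.0
    return float(norm.sf((threshold - mu) / sigma))


def _roma_high_prob(mm: MarkerModel, meno: str, thresholds: Thresholds) -> float:
    a, b_he4, b_ca = ROMA_COEFFICIENTS[meno]
    cut = thresholds.roma_cut(meno) / 100.0
    pi0 = float(np.log(cut / (1 - cut)))
    mean = a + b_he4 * mm.he4_mu + b_ca * mm.ca125_mu
    sd = float(np.hypot(b_he4 * mm.he4_sigma, b_ca * mm.ca125_sigma))
    return _normal_tail(pi0, mean, sd)


def _rmi_high_prob(p_u: dict[float, float], mm: MarkerModel, meno: str, thresholds: Thresholds) -> float:
    m = RMI_MENOPAUSAL_SCORE[meno]
    total = 0.0
    for u, pu in p_u.items():
        if u == 0.0 or pu == 0.0:
            continue
        ca_cut = float(np.log(thresholds.rmi_cut / (u * m)))
        total += pu * _normal_tail(ca_cut, mm.ca125_mu, mm.ca125_sigma)
    return total


def analytic_operating_points(
    params: GeneratorParams, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Exact sensitivity/specificity of every strategy under ``params``.

    Closed-form under the generator's independence structure: feature
    patterns are enumerated exactly and marker thresholds reduce to normal
    tail probabilities on the log scale.  Returned as a strategy-indexed
    frame with ``sensitivity`` and ``specificity`` columns; ``IOTA_ONLY``
    is conditional on its conclusive stratum.
    """
    validate_params(params)
    feat = {c: _feature_distribution(params.features[c]) for c in TRUTH_CLASSES}

    # P(call = high | class, meno) per strategy; IOTA_ONLY tracked jointly
    # with conclusiveness for the stratum-conditional aggregate.
    p_high: dict[str, dict[str, float]] = {}
    p_malcall: dict[str, float] = {}
    p_conclusive: dict[str, float] = {}
    for c in TRUTH_CLASSES:
        fd = feat[c]
        malcall = fd["call"]["malignant"]
        inc = fd["call"]["inconclusive"]
        p_malcall[c] = malcall
        p_conclusive[c] = 1.0 - inc
        expert_high = params.expert_sens if c != "benign" else 1 - params.expert_spec
        per_strategy = {s: 0.0 for s in ("IOTA_EXPERT", "IOTA_ROMA", "IOTA_RMI", "ROMA_ALONE", "RMI_ALONE")}
        for meno, w in (("pre", params.premenopausal_frac), ("post", 1 - params.premenopausal_frac)):
            mm = params.markers[c][meno]
            roma_p = _roma_high_prob(mm, meno, thresholds)
            rmi_p = _rmi_high_prob(fd["u"], mm, meno, thresholds)
            rmi_inc_p = _rmi_high_prob(fd["inc_u"], mm, meno, thresholds)  # joint with inconclusive
            per_strategy["IOTA_EXPERT"] += w * (malcall + inc * expert_high)
            per_strategy["IOTA_ROMA"] += w * (malcall + inc * roma_p)
            per_strategy["IOTA_RMI"] += w * (malcall + rmi_inc_p)
            per_strategy["ROMA_ALONE"] += w * roma_p
            per_strategy["RMI_ALONE"] += w * rmi_p
        p_high[c] = per_strategy

    bf = params.borderline_frac
    mal_weights = {"malignant": 1 - bf, "borderline": bf}

    rows = []
    for strategy in ("IOTA_EXPERT", "IOTA_ROMA", "IOTA_RMI", "ROMA_ALONE", "RMI_ALONE"):
        sens = sum(w * p_high[c][strategy] for c, w in mal_weights.items())
        spec = 1.0 - p_high["benign"][strategy]
        rows.append({"strategy": strategy, "sensitivity": sens, "specificity": spec})
    # IOTA_ONLY: conditional on the conclusive stratum
    sens_num = sum(w * p_malcall[c] for c, w in mal_weights.items())
    sens_den = sum(w * p_conclusive[c] for c, w in mal_weights.items())
    spec_num = p_conclusive["benign"] - p_malcall["benign"]
    rows.append({
        "strategy": "IOTA_ONLY",
        "sensitivity": sens_num / sens_den,
        "specificity": spec_num / p_conclusive["benign"],
    })
    return pd.DataFrame(rows).set_index("strategy")


def analytic_marginals(params: GeneratorParams) -> dict[str, float]:
    """Closed-form population marginals implied by ``params``."""
    validate_params(params)
    bf = params.borderline_frac
    inc = {c: _feature_distribution(params.features[c])["call"]["inconclusive"] for c in TRUTH_CLASSES}
    inc_mal = (1 - bf) * inc["malignant"] + bf * inc["borderline"]
    prev = params.prevalence
    return {
        "prevalence": prev,
        "premenopausal_frac": params.premenopausal_frac,
        "inconclusive_rate": prev * inc_mal + (1 - prev) * inc["benign"],
        "inconclusive_rate_malignant": inc_mal,
        "inconclusive_rate_benign": inc["benign"],
    }
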