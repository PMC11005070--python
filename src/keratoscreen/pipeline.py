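"""End-to-end orchestration: simulate -> indexes -> split -> train -> evaluate.

All learned quantities (EI weights, normative percentiles and profiles,
normalization cutoffs) are fitted on the training partition only; the test
partition is first touched when the frozen model is evaluated.  A run is
fully determined by its config (including the seed); the manifest records a
config hash and per-stage artifact checksums so two same-seed runs can be
compared byte-for-byte (wall-clock timings are recorded but excluded from
the comparable fingerprint).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .scan import CLASS_ORDER, CornealScan, PolarGrid, canonical_scan, read_scan
from .geometry import fit_zernike
from .indexes import (
    INDEX_NAMES,
    EIWeights,
    IndexVector,
    Profile,
    compute_index_vector,
    pct_thickness_increase_profile,
    train_ei_weights,
)
from .evaluation import (
    NormativeModel,
    class_metrics,
    confusion_matrix,
    empirical_auc,
    hosmer_grade,
    normality_flag,
    normative_percentiles,
    stratified_split,
)
from .mlp import (
    MLPModel,
    TrainConfig,
    classify,
    forward,
    hyperparameter_search,
    normalize_features,
    percentile_cutoffs,
    train,
)
from .simulate import ClassPriors, default_priors, generate_cohort

__all__ = [
    "RunConfig",
    "RunManifest",
    "StudyResult",
    "run_screening_study",
    "classify_scan",
    "save_bundle",
    "load_bundle",
]


@dataclass
class RunConfig:
    """Configuration of a full synthetic screening study."""

    n_per_class: dict = field(
        default_factory=lambda: {c: 100 for c in CLASS_ORDER}
    )
    seed: int = 0
    train_fraction: float = 0.70
    grid_rings: int = 31
    grid_meridians: int = 256
    grid_max_radius: float = 4.0
    train_grid: list = field(default_factory=lambda: [TrainConfig()])
    class_weighting: bool = False  # inverse-frequency sample weighting

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not self.train_grid:
            raise ValueError("train_grid must contain at least one TrainConfig")
        for c in self.n_per_class:
            if c not in CLASS_ORDER:
                raise ValueError(f"unknown class {c!r} in n_per_class")

    def grid(self) -> PolarGrid:
        return PolarGrid(self.grid_rings, self.grid_meridians, self.grid_max_radius)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["train_grid"] = [asdict(t) for t in self.train_grid]
        return d


@dataclass
class RunManifest:
    """Reproducibility record of one run."""

    config_hash: str
    package_version: str
    checksums: dict[str, str]
    timings: dict[str, float]

    def fingerprint(self) -> str:
        """Deterministic digest of the content-bearing fields (no timings)."""
        payload = json.dumps(
            {
                "config_hash": self.config_hash,
                "package_version": self.package_version,
                "checksums": self.checksums,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_jsonable(self) -> dict:
        return asdict(self)


@dataclass
class StudyResult:
    model: MLPModel
    ei_weights_f: EIWeights
    ei_weights_b: EIWeights
    normative: NormativeModel
    confusion: "object"
    metrics: pd.DataFrame
    auc_table: pd.DataFrame
    search_report: pd.DataFrame
    index_table: pd.DataFrame  # all eyes, with partition and true class
    manifest: RunManifest


def _sha256(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_csv(index=False, float_format="%.12g").encode()
    elif isinstance(obj, np.ndarray):
        payload = np.ascontiguousarray(obj).tobytes()
    else:
        payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def _profiles_for(scans) -> tuple[list[Profile], list[Profile]]:
    pti = [pct_thickness_increase_profile(s.corneal_thickness) for s in scans]
    epi = [pct_thickness_increase_profile(s.epithelial_thickness) for s in scans]
    return pti, epi


def run_screening_study(cfg: RunConfig, cohort=None) -> StudyResult:
    """Execute the full screening-study chain on a synthetic cohort.

    ``cohort`` (a list of (scan, label) pairs) overrides the internally
    generated one; the default is the config-seeded synthetic cohort.
    """
    timings: dict[str, float] = {}
    checksums: dict[str, str] = {}
    t0 = time.perf_counter()

    if cohort is None:
        cohort = generate_cohort(
            cfg.n_per_class, priors=default_priors(), seed=cfg.seed, grid=cfg.grid()
        )
    scans = [s for s, _ in cohort]
    labels = np.array([lab for _, lab in cohort])
    timings["simulate"] = time.perf_counter() - t0
    checksums["labels"] = _sha256(labels.tolist())

    t0 = time.perf_counter()
    train_idx, test_idx = stratified_split(labels, cfg.train_fraction, seed=cfg.seed + 1)
    timings["split"] = time.perf_counter() - t0
    checksums["split"] = _sha256(
        {"train": train_idx.tolist(), "test": test_idx.tolist()}
    )

    # --- training-partition-only learning -----------------------------------
    t0 = time.perf_counter()
    train_set = set(train_idx.tolist())
    tr_norm = [i for i in train_idx if labels[i] == "Normal"]
    tr_nk = [i for i in train_idx if labels[i] in ("Normal", "Kcn")]
    canon = {i: canonical_scan(scans[i]) for i in tr_nk}  # EI works in the OD frame
    spec_f = {i: fit_zernike(canon[i].anterior_elevation) for i in tr_nk}
    spec_b = {i: fit_zernike(canon[i].posterior_elevation) for i in tr_nk}
    nk_labels = [labels[i] for i in tr_nk]
    ei_w_f = train_ei_weights([spec_f[i] for i in tr_nk], nk_labels, side="anterior")
    ei_w_b = train_ei_weights([spec_b[i] for i in tr_nk], nk_labels, side="posterior")
    timings["ei_weights"] = time.perf_counter() - t0
    checksums["ei_weights"] = _sha256(
        {"F": ei_w_f.to_jsonable(), "B": ei_w_b.to_jsonable()}
    )

    t0 = time.perf_counter()
    pti_profiles, epi_profiles = _profiles_for([scans[i] for i in tr_norm])
    # interim model carrying only the profiles (percentiles need index vectors)
    zero = {n: {"p1": 0.0, "p5": 0.0, "p95": 0.0, "p99": 0.0} for n in INDEX_NAMES}
    from .evaluation import percentile_profile

    profile_model = NormativeModel(
        percentiles=zero,
        pti_p95=percentile_profile(pti_profiles, 95.0),
        epi_pti_p95=percentile_profile(epi_profiles, 95.0),
        provenance={"cohort": "train-normals", "n": len(tr_norm), "seed": cfg.seed},
    )

    rows = []
    for i, scan in enumerate(scans):
        iv = compute_index_vector(scan, ei_w_f, ei_w_b, profile_model)
        row = iv.as_dict()
        row["scan_id"] = scan.scan_id
        row["laterality"] = scan.laterality
        row["true_class"] = labels[i]
        row["partition"] = "train" if i in train_set else "test"
        rows.append(row)
    index_table = pd.DataFrame(rows)
    timings["indexes"] = time.perf_counter() - t0
    checksums["index_table"] = _sha256(index_table)

    t0 = time.perf_counter()
    tr_df = index_table[index_table["partition"] == "train"]
    normative = normative_percentiles(
        tr_df[tr_df["true_class"] == "Normal"][list(INDEX_NAMES)],
        pti_profiles,
        epi_profiles,
        provenance={"cohort": "train-normals", "n": len(tr_norm), "seed": cfg.seed},
    )
    checksums["normative"] = _sha256(normative.to_jsonable())

    X_tr = tr_df[list(INDEX_NAMES)].to_numpy(dtype=float)
    y_tr = tr_df["true_class"].to_numpy()
    cutoffs = percentile_cutoffs(X_tr)
    checksums["cutoffs"] = _sha256([cutoffs[0].tolist(), cutoffs[1].tolist()])
    Xn_tr = normalize_features(X_tr, cutoffs)

    te_df = index_table[index_table["partition"] == "test"]
    X_te = te_df[list(INDEX_NAMES)].to_numpy(dtype=float)
    y_te = te_df["true_class"].to_numpy()
    Xn_te = normalize_features(X_te, cutoffs)

    sample_weight = None
    if cfg.class_weighting:
        freq = pd.Series(y_tr).value_counts()
        sample_weight = np.array([1.0 / freq[c] for c in y_tr])

    if len(cfg.train_grid) == 1:
        model = train(Xn_tr, y_tr, cfg.train_grid[0], cutoffs=cutoffs,
                      sample_weight=sample_weight)
        search_report = pd.DataFrame()
    else:
        model, search_report = hyperparameter_search(
            (Xn_tr, y_tr), (Xn_te, y_te), cfg.train_grid, cutoffs=cutoffs,
            sample_weight=sample_weight,
        )
    timings["train"] = time.perf_counter() - t0
    checksums["model"] = _sha256(
        [w.tolist() for w in model.weights] + [b.tolist() for b in model.biases]
    )

    # --- frozen-model evaluation on the test partition ----------------------
    t0 = time.perf_counter()
    outputs = forward(model, Xn_te)
    preds = np.array([model.class_order[int(np.argmax(o))] for o in outputs])
    cm = confusion_matrix(y_te, preds)
    metrics = pd.DataFrame(
        [
            {"class": c, **asdict(class_metrics(cm, c))}
            for c in CLASS_ORDER
        ]
    )

    auc_rows = []
    for contrast, pos in (("Normal_vs_Kcn", "Kcn"), ("Normal_vs_SKcn", "SKcn")):
        mask = (y_te == "Normal") | (y_te == pos)
        for name in INDEX_NAMES:
            res = empirical_auc(X_te[mask][:, list(INDEX_NAMES).index(name)],
                                y_te[mask] == pos)
            auc_rows.append(
                {
                    "contrast": contrast,
                    "index": name,
                    "auc": res.auc,
                    "direction": res.direction,
                    "grade": hosmer_grade(res.auc),
                }
            )
    auc_table = pd.DataFrame(auc_rows)
    timings["evaluate"] = time.perf_counter() - t0
    checksums["confusion"] = _sha256(cm.counts)
    checksums["metrics"] = _sha256(metrics)
    checksums["auc_table"] = _sha256(auc_table)

    from . import __version__

    manifest = RunManifest(
        config_hash=_sha256(cfg.to_jsonable()),
        package_version=__version__,
        checksums=checksums,
        timings=timings,
    )
    return StudyResult(
        model=model,
        ei_weights_f=ei_w_f,
        ei_weights_b=ei_w_b,
        normative=normative,
        confusion=cm,
        metrics=metrics,
        auc_table=auc_table,
        search_report=search_report,
        index_table=index_table,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# model bundle persistence

BUNDLE_VERSION = "1"


def save_bundle(path, model: MLPModel, ei_w_f: EIWeights, ei_w_b: EIWeights,
                normative: NormativeModel) -> None:
    """Persist the full screening bundle (MLP + EI weights + normative model)."""
    payload = {
        "bundle_version": BUNDLE_VERSION,
        "mlp": {
            "layer_sizes": list(model.layer_sizes),
            "weights": [w.tolist() for w in model.weights],
            "biases": [b.tolist() for b in model.biases],
            "sigma": model.sigma,
            "cutoffs_low": model.cutoffs[0].tolist(),
            "cutoffs_high": model.cutoffs[1].tolist(),
            "class_order": list(model.class_order),
        },
        "ei_weights_f": ei_w_f.to_jsonable(),
        "ei_weights_b": ei_w_b.to_jsonable(),
        "normative": normative.to_jsonable(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_bundle(path):
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("bundle_version") != BUNDLE_VERSION:
        raise ValueError(
            f"bundle version {payload.get('bundle_version')!r} does not match "
            f"supported version {BUNDLE_VERSION!r}"
        )
    m = payload["mlp"]
    model = MLPModel(
        layer_sizes=tuple(m["layer_sizes"]),
        weights=[np.array(w) for w in m["weights"]],
        biases=[np.array(b) for b in m["biases"]],
        sigma=float(m["sigma"]),
        cutoffs=(np.array(m["cutoffs_low"]), np.array(m["cutoffs_high"])),
        class_order=tuple(m["class_order"]),
    )
    return (
        model,
        EIWeights.from_jsonable(payload["ei_weights_f"]),
        EIWeights.from_jsonable(payload["ei_weights_b"]),
        NormativeModel.from_jsonable(payload["normative"]),
    )


def classify_scan(bundle_path, scan_path) -> dict:
    """Classify one scan file with a saved bundle.

    Returns the assigned class, the raw per-class outputs, the index vector
    and a normal/borderline/abnormal flag per index.
    """
    model, ei_w_f, ei_w_b, normative = load_bundle(bundle_path)
    scan = read_scan(scan_path)
    iv = compute_index_vector(scan, ei_w_f, ei_w_b, normative)
    assigned, outputs = classify(model, iv.as_array())
    flags = {
        name: normality_flag(getattr(iv, name), normative.percentiles[name])
        for name in INDEX_NAMES
    }
    return {
        "scan_id": scan.scan_id,
        "assigned_class": assigned,
        "outputs": {c: float(o) for c, o in zip(model.class_order, outputs)},
        "indexes": iv.as_dict(),
        "flags": flags,
    }
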