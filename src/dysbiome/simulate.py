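"""Synthetic matched-pair cohorts with the statistical structure the analysis
pipeline assumes.

The generator emulates a case/control 16S study in which every case (PWH) has
exactly one control (SN) matched for subgroup (F / MSM / MSW), birth country,
and near-identical age and BMI.  Counts follow a per-taxon gamma-Poisson
model: a lognormal baseline composition is tilted multiplicatively by
log-linear group effects (HIV status, MSM membership, recent receptive anal
intercourse), cases optionally receive an evenness penalty that lowers alpha
diversity, sequencing depth varies lognormally around its mean, and
per-taxon gamma noise supplies the overdispersion.  Clinical markers are
linear functions of each sample's *true* dysbiosis index (computed from the
configured effect sets on the noise-free composition) plus Gaussian noise;
the comorbidity count thresholds a latent Gaussian into {0, 1, >=2}.

Sequences are random ACGT strings (no sequence-level realism) and taxonomy
strings are synthetic placeholders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AsvTable, md5_asv_id

_SUBGROUPS = ("F", "MSM", "MSW")


@dataclass
class ClinicalCoupling:
    """Slopes linking a sample's true DI to its simulated clinical markers."""

    nadir_cd4_mean: float = 350.0
    nadir_cd4_slope: float = -120.0     # cells/mm3 per DI unit (PWH only)
    nadir_cd4_sd: float = 80.0
    pre_art_cd4_mean: float = 420.0
    pre_art_cd4_slope: float = -100.0
    pre_art_cd4_sd: float = 110.0
    supar_mean: float = 0.0             # z-scale units
    supar_slope: float = 0.8
    supar_sd: float = 1.0
    scd14_mean: float = 0.0
    scd14_slope: float = 0.5
    scd14_sd: float = 1.0
    comorbidity_slope: float = 0.9      # on the latent Gaussian


def _default_n_pairs() -> dict:
    # mirrors the paired cohort: 36 F, 72 MSM, 34 MSW samples
    return {"F": 18, "MSM": 36, "MSW": 17}


def _default_hiv_effect() -> dict:
    return {**{i: 1.2 for i in range(0, 25)}, **{i: -1.2 for i in range(25, 50)}}


def _default_msm_effect() -> dict:
    # indices 25-34 overlap the HIV-depleted set with the OPPOSITE sign:
    # taxa depleted in cases but enriched in MSM
    return {**{i: 1.0 for i in range(50, 80)},
            **{i: -1.0 for i in range(80, 100)},
            **{i: 1.0 for i in range(25, 35)}}


def _default_rai_effect() -> dict:
    return {i: 0.8 for i in range(50, 65)}


def _default_rai_prob() -> dict:
    return {"F": 0.13, "MSM": 0.55, "MSW": 0.0}


@dataclass
class CohortConfig:
    """Parameters of the synthetic matched cohort.

    Effects are mappings from ASV index (0-based position in the generated
    table) to natural-log fold shifts on expected relative abundance; they
    act multiplicatively before depth scaling, so a value of ln 2 doubles the
    expected relative abundance in the affected samples.
    """

    n_pairs: dict = field(default_factory=_default_n_pairs)
    n_asvs: int = 300
    sequencing_depth_mean: float = 40_000.0
    depth_sigma: float = 0.25           # lognormal sd of per-sample depth
    dispersion: float = 0.5             # gamma-Poisson overdispersion (0 = Poisson)
    baseline_sigma: float = 1.5         # lognormal spread of the baseline composition
    hiv_effect: dict = field(default_factory=_default_hiv_effect)
    msm_effect: dict = field(default_factory=_default_msm_effect)
    rai_effect: dict = field(default_factory=_default_rai_effect)
    opposing_overlap: bool = True       # require hiv/msm overlap signs to oppose
    diversity_penalty_case: float = 0.08
    rai_prob: dict = field(default_factory=_default_rai_prob)
    clinical: ClinicalCoupling = field(default_factory=ClinicalCoupling)
    sequence_length: int = 250
    seed: int = 0

    def validate(self) -> None:
        if self.n_asvs <= 0:
            raise ValueError("n_asvs must be positive")
        if not self.n_pairs or any(v < 0 for v in self.n_pairs.values()) \
                or sum(self.n_pairs.values()) == 0:
            raise ValueError("n_pairs must contain at least one positive subgroup size")
        if set(self.n_pairs) - set(_SUBGROUPS):
            raise ValueError(f"subgroups must be among {_SUBGROUPS}")
        if self.sequencing_depth_mean <= 0:
            raise ValueError("sequencing_depth_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name, eff in (("hiv_effect", self.hiv_effect),
                          ("msm_effect", self.msm_effect),
                          ("rai_effect", self.rai_effect)):
            for idx, lfc in eff.items():
                if not 0 <= idx < self.n_asvs:
                    raise ValueError(f"{name}: ASV index {idx} outside 0..{self.n_asvs - 1}")
                if lfc == 0:
                    raise ValueError(f"{name}: zero effect at index {idx}")
        if self.opposing_overlap:
            for idx in set(self.hiv_effect) & set(self.msm_effect):
                if np.sign(self.hiv_effect[idx]) == np.sign(self.msm_effect[idx]):
                    raise ValueError(
                        f"hiv/msm overlap at index {idx} must have opposite signs "
                        "(set opposing_overlap=False to allow)"
                    )

    def asdict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "clinical"}
        d = {k: ({str(i): f for i, f in v.items()} if isinstance(v, dict) and k.endswith("_effect") else v)
             for k, v in d.items()}
        d["clinical"] = dict(self.clinical.__dict__)
        return d


@dataclass
class Cohort:
    """Generated cohort: counts, metadata, tree, clinical table, and truth."""

    table: AsvTable
    metadata: pd.DataFrame
    tree_newick: str
    clinical: pd.DataFrame
    truth: dict

    def __iter__(self):
        return iter((self.table, self.metadata, self.tree_newick, self.clinical))


def _effect_vector(effect: dict, n_asvs: int) -> np.ndarray:
    v = np.zeros(n_asvs)
    for idx, lfc in effect.items():
        v[idx] = lfc
    return v


def _random_tree(asv_ids: list[str], rng: np.random.Generator) -> str:
    """Random binary tree over the ASVs, exponential branch lengths."""
    if len(asv_ids) == 1:
        return f"({asv_ids[0]}:1.000000);"
    nodes = list(asv_ids)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        bl = rng.exponential(0.1, size=2)
        merged = f"({nodes[i]}:{bl[0]:.6f},{nodes[j]}:{bl[1]:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cohort; identical config and seed give identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_asvs

    baseline = np.exp(rng.normal(0.0, config.baseline_sigma, size=n))
    hiv_vec = _effect_vector(config.hiv_effect, n)
    msm_vec = _effect_vector(config.msm_effect, n)
    rai_vec = _effect_vector(config.rai_effect, n)

    # --- sample frame: one matched control per case -----------------------
    rows = []
    for g in _SUBGROUPS:
        for i in range(config.n_pairs.get(g, 0)):
            pair_id = f"pair_{g}{i + 1:03d}"
            birth = "NL" if rng.random() < 0.85 else "other"
            age = rng.uniform(45.0, 70.0)
            bmi = rng.normal(24.5, 3.0)
            p_rai = config.rai_prob.get(g, 0.0)
            for status, suffix in (("PWH", "P"), ("SN", "N")):
                rai = "RAI+" if rng.random() < p_rai else "RAI-"
                rows.append({
                    "sample_id": f"{g}{i + 1:03d}{suffix}",
                    "hiv_status": status,
                    "subgroup": g,
                    "pair_id": pair_id,
                    "rai": rai,
                    "birth_country": birth,
                    "age": round(age + rng.normal(0.0, 0.5), 1),
                    "bmi": round(bmi + rng.normal(0.0, 0.3), 1),
                })
    metadata = pd.DataFrame(rows).set_index("sample_id")

    # --- expected compositions and counts ---------------------------------
    n_samples = len(metadata)
    P = np.empty((n_samples, n))
    for s, (sid, md) in enumerate(metadata.iterrows()):
        logw = np.log(baseline).copy()
        if md["hiv_status"] == "PWH":
            logw += hiv_vec
        if md["subgroup"] == "MSM":
            logw += msm_vec
        if md["rai"] == "RAI+":
            logw += rai_vec
        if md["hiv_status"] == "PWH" and config.diversity_penalty_case > 0:
            logw *= 1.0 + config.diversity_penalty_case
        w = np.exp(logw - logw.max())
        P[s] = w / w.sum()

    mu_log = np.log(config.sequencing_depth_mean) - config.depth_sigma**2 / 2
    depths = np.maximum(rng.lognormal(mu_log, config.depth_sigma, size=n_samples), 1.0)
    counts = np.empty((n_samples, n), dtype=np.int64)
    for s in range(n_samples):
        lam = depths[s] * P[s]
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            lam = lam * rng.gamma(shape, config.dispersion, size=n)
        counts[s] = rng.poisson(lam)
        if counts[s].sum() == 0:            # vanishingly rare at realistic depth
            counts[s, int(np.argmax(P[s]))] = 1

    # --- identifiers, taxonomy, tree --------------------------------------
    seqs = ["".join(rng.choice(list("ACGT"), size=config.sequence_length))
            for _ in range(n)]
    asv_ids = [md5_asv_id(s)[0] for s in seqs]
    phyla = [f"Phylum{rng.integers(1, 6)}" for _ in range(n)]
    families = [f"Family{rng.integers(1, 31)}" for _ in range(n)]
    taxonomy = pd.Series(
        [f"Bacteria;{p};{f};ASV" for p, f in zip(phyla, families)],
        index=pd.Index(asv_ids, name="asv_id"), name="taxonomy")
    sequences = pd.Series(seqs, index=pd.Index(asv_ids, name="asv_id"), name="sequence")
    table = AsvTable(pd.DataFrame(counts, index=metadata.index, columns=asv_ids),
                     taxonomy=taxonomy, sequences=sequences)
    tree_newick = _random_tree(asv_ids, rng)

    # --- true DI and coupled clinical markers ------------------------------
    enriched_idx = [i for i, f in config.hiv_effect.items() if f > 0]
    depleted_idx = [i for i, f in config.hiv_effect.items() if f < 0]
    if enriched_idx and depleted_idx:
        true_di = (np.log10(P[:, enriched_idx]).mean(axis=1)
                   - np.log10(P[:, depleted_idx]).mean(axis=1))
    else:
        true_di = np.zeros(n_samples)

    cc = config.clinical
    is_case = (metadata["hiv_status"] == "PWH").to_numpy()
    nadir = cc.nadir_cd4_mean + cc.nadir_cd4_slope * true_di \
        + rng.normal(0.0, cc.nadir_cd4_sd, n_samples)
    pre_art = cc.pre_art_cd4_mean + cc.pre_art_cd4_slope * true_di \
        + rng.normal(0.0, cc.pre_art_cd4_sd, n_samples)
    supar = cc.supar_mean + cc.supar_slope * true_di + rng.normal(0.0, cc.supar_sd, n_samples)
    scd14 = cc.scd14_mean + cc.scd14_slope * true_di + rng.normal(0.0, cc.scd14_sd, n_samples)
    sd_di = true_di.std()
    z_di = (true_di - true_di.mean()) / sd_di if sd_di > 0 else np.zeros(n_samples)
    latent = cc.comorbidity_slope * z_di + rng.normal(0.0, 1.0, n_samples)
    comorb = np.digitize(latent, [0.8, 1.6])
    clinical = pd.DataFrame({
        "true_di": true_di,
        "nadir_cd4": np.where(is_case, np.maximum(np.round(nadir), 5.0), np.nan),
        "pre_art_cd4": np.where(is_case, np.maximum(np.round(pre_art), 5.0), np.nan),
        "supar": supar,
        "scd14": scd14,
        "n_comorbidities": comorb,
    }, index=metadata.index)

    truth = {
        "enriched_ids": [asv_ids[i] for i in enriched_idx],
        "depleted_ids": [asv_ids[i] for i in depleted_idx],
        "msm_ids": [asv_ids[i] for i in sorted(config.msm_effect)],
        "rai_ids": [asv_ids[i] for i in sorted(config.rai_effect)],
        "true_di": pd.Series(true_di, index=metadata.index, name="true_di"),
    }
    return Cohort(table, metadata, tree_newick, clinical, truth)
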