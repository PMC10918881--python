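"""Synthetic multi-patient, multi-tissue BCR repertoires.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is exercisable without sequencing data:

* CDR3 amino-acid sequences are random strings over the 20-letter
  alphabet flanked by the canonical ``C...W`` junction motif; a
  configurable fraction of clonotypes is instead drawn from a pool of
  planted cluster seeds and point-mutated, so that intra-cluster
  Levenshtein distances stay small while background sequences almost
  never collide;
* clone sizes follow a skewed law (geometric by default);
* heavy-chain isotypes follow per-tissue (and, in single-cell mode,
  per-cell-type) probability profiles;
* light-chain locus is kappa with probability ``kappa_prob`` (default
  2/3, the physiological kappa:lambda ratio of roughly 2:1), with
  between-sample heterogeneity;
* for pSS samples, the disease-activity score (ESSDAI) is linearly
  coupled to the sample's realised read-weighted kappa-lambda ratio with
  additive Gaussian noise, either at an explicit noise level or at a
  requested latent correlation (``target_r``).

Everything is a deterministic function of the config, including its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import ISOTYPES, BCell, ChainRecord, RepertoireSample

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: one fixed codon per residue, for synthesising a consistent CDR3nt
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_V_GENES = {
    "IGH": ["IGHV1-2", "IGHV1-69", "IGHV3-23", "IGHV3-30", "IGHV4-34", "IGHV4-59", "IGHV5-51"],
    "IGK": ["IGKV1-39", "IGKV3-20", "IGKV4-1", "IGKV1-5"],
    "IGL": ["IGLV1-44", "IGLV2-14", "IGLV3-21"],
}
_J_GENES = {
    "IGH": ["IGHJ4", "IGHJ6", "IGHJ3", "IGHJ5"],
    "IGK": ["IGKJ1", "IGKJ2", "IGKJ4"],
    "IGL": ["IGLJ2", "IGLJ3"],
}
_LIGHT_C = {"IGK": "IGKC", "IGL": "IGLC2"}


class ConfigError(ValueError):
    """Raised for an internally inconsistent simulation config."""


def default_isotype_profile() -> dict:
    """Per-population isotype probabilities over the nine IgH classes.

    Keys are ``(tissue_class, cell_type)`` for single-cell populations and
    ``(tissue_class, "bulk")`` for bulk chains, with ``tissue_class`` in
    ``{"PB", "SG"}``. Naive cells are dominated by IgM/IgD; switched
    populations carry IgG/IgA, with IgA enriched in glands.
    """
    naive = dict(zip(ISOTYPES, [0.58, 0.40, 0.005, 0.005, 0.004, 0.001, 0.003, 0.002, 0.0]))
    return {
        ("PB", "bulk"): dict(zip(ISOTYPES, [0.30, 0.08, 0.22, 0.10, 0.05, 0.02, 0.13, 0.095, 0.005])),
        ("SG", "bulk"): dict(zip(ISOTYPES, [0.12, 0.03, 0.30, 0.08, 0.05, 0.02, 0.25, 0.145, 0.005])),
        ("PB", "naive"): dict(naive),
        ("SG", "naive"): dict(naive),
        ("PB", "memory"): dict(zip(ISOTYPES, [0.20, 0.02, 0.25, 0.12, 0.06, 0.02, 0.15, 0.17, 0.01])),
        ("SG", "memory"): dict(zip(ISOTYPES, [0.15, 0.02, 0.30, 0.07, 0.06, 0.02, 0.25, 0.12, 0.01])),
        ("PB", "plasma"): dict(zip(ISOTYPES, [0.08, 0.01, 0.32, 0.12, 0.06, 0.03, 0.20, 0.17, 0.01])),
        ("SG", "plasma"): dict(zip(ISOTYPES, [0.06, 0.01, 0.35, 0.10, 0.06, 0.03, 0.22, 0.16, 0.01])),
    }


def default_cell_type_profile() -> dict:
    """Per-tissue cell-type mix; naive cells under-represented in glands."""
    return {
        "PB": {"naive": 0.45, "memory": 0.40, "plasma": 0.15},
        "SG": {"naive": 0.15, "memory": 0.50, "plasma": 0.35},
    }


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    ``mode`` selects bulk (unpaired chains with read counts) or
    single-cell (paired-chain cells) output. ``n_chains`` is the number of
    heavy-chain clonotype rows per bulk sample (an equal number of light
    chains is generated); ``n_cells`` the number of cells per single-cell
    sample.
    """

    n_patients: int = 10
    tissues: tuple[str, ...] = ("SG_labial", "SG_parotid")
    mode: str = "bulk"  # bulk | single_cell
    pss_fraction: float = 0.5
    n_chains: int = 1000
    n_cells: int = 600
    clone_size_law: tuple[str, float] = ("geometric", 0.35)
    n_cluster_seeds: int = 25
    cluster_mutation_rate: int = 1
    cluster_membership_prob: float = 0.05
    cdr3_length_range: tuple[int, int] = (12, 18)
    isotype_profile: dict = field(default_factory=default_isotype_profile)
    cell_type_profile: dict = field(default_factory=default_cell_type_profile)
    #: multipliers applied to pSS samples' isotype profile (renormalised);
    #: e.g. {"IGHA2": 0.3} depresses IgA2 usage in the case group
    isotype_case_multiplier: Optional[dict] = None
    kappa_prob: float = 2.0 / 3.0
    kappa_prob_sd: float = 0.05
    #: fraction of a sample's clonotypes drawn from a patient-shared pool,
    #: producing clonal overlap between tissues of the same patient
    tissue_overlap: float = 0.3
    #: ESSDAI = slope * (kappa/lambda ratio) + intercept + N(0, noise_sd),
    #: truncated at 0, for pSS samples. If target_r is set, noise_sd is
    #: derived from the realised between-sample ratio spread so the latent
    #: correlation equals target_r.
    essdai_slope: float = 5.0
    essdai_intercept: float = 2.0
    essdai_noise_sd: Optional[float] = None
    essdai_target_r: Optional[float] = 0.6
    #: prefix for generated patient identifiers (P01, P02, ...)
    patient_prefix: str = "P"
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.mode not in ("bulk", "single_cell"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.kappa_prob <= 1.0:
            raise ConfigError("kappa_prob must lie in [0, 1]")
        if self.cdr3_length_range[0] < 5:
            raise ConfigError("cdr3 lengths must be >= 5")
        if not 0 <= self.cluster_mutation_rate <= 3:
            raise ConfigError("cluster_mutation_rate must be an integer in 0..3")
        if not 0.0 <= self.cluster_membership_prob <= 1.0:
            raise ConfigError("cluster_membership_prob must lie in [0, 1]")
        name, _ = self.clone_size_law
        if name != "geometric":
            raise ConfigError(f"unsupported clone_size_law {name!r}")
        for key, profile in self.isotype_profile.items():
            total = sum(profile.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"isotype profile {key} sums to {total}, not 1")
        for key, profile in self.cell_type_profile.items():
            if abs(sum(profile.values()) - 1.0) > 1e-9:
                raise ConfigError(f"cell-type profile {key} does not sum to 1")
        if self.essdai_target_r is not None and not 0.0 < abs(self.essdai_target_r) <= 1.0:
            raise ConfigError("essdai_target_r must lie in (0, 1]")


def _tissue_class(tissue: str) -> str:
    return "PB" if tissue == "PB" else "SG"


def _random_cdr3(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    middle = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length - 2))
    return "C" + middle + "W"


def _mutate(seq: str, n_edits: int, rng: np.random.Generator) -> str:
    """Apply n_edits point substitutions at interior positions (the C/W
    flanks are preserved), each to a residue different from the original."""
    chars = list(seq)
    if n_edits == 0 or len(chars) <= 2:
        return seq
    positions = rng.choice(np.arange(1, len(chars) - 1), size=min(n_edits, len(chars) - 2), replace=False)
    for pos in positions:
        old = chars[pos]
        choices = [a for a in AA_ALPHABET if a != old]
        chars[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def _nt_for(aa: str) -> str:
    return "".join(_CODON[ch] for ch in aa)


def _clone_size(rng: np.random.Generator, law: tuple[str, float]) -> int:
    _, p = law
    return int(rng.geometric(p))


def _profile_for(config: SimConfig, tissue: str, cell_type: str, group: str) -> tuple[list, np.ndarray]:
    profile = dict(config.isotype_profile[(_tissue_class(tissue), cell_type)])
    if group == "pSS" and config.isotype_case_multiplier:
        for iso, mult in config.isotype_case_multiplier.items():
            profile[iso] = profile.get(iso, 0.0) * mult
        total = sum(profile.values())
        profile = {k: v / total for k, v in profile.items()}
    names = list(ISOTYPES)
    probs = np.array([profile.get(n, 0.0) for n in names])
    return names, probs / probs.sum()


class _ClonotypeFactory:
    """Draws heavy/light clonotypes for one patient, mixing three sources:
    planted cluster seeds (cohort-wide), a patient-shared pool (tissue
    overlap), and fresh background sequences."""

    def __init__(
        self,
        config: SimConfig,
        rng: np.random.Generator,
        seeds: list[str],
        kappa_p: float,
    ):
        self.config = config
        self.rng = rng
        self.seeds = seeds
        self._kappa_p = kappa_p
        pool_size = max(40, config.n_chains // 4)
        self.shared_heavy = [self._fresh("IGH") for _ in range(pool_size)]
        self.shared_light = [self._fresh("light") for _ in range(pool_size)]

    def _fresh(self, kind: str) -> tuple[str, str, str, str]:
        cfg, rng = self.config, self.rng
        lo, hi = cfg.cdr3_length_range
        if kind == "IGH":
            if self.seeds and rng.random() < cfg.cluster_membership_prob:
                seed = self.seeds[int(rng.integers(0, len(self.seeds)))]
                n_edits = int(rng.integers(0, cfg.cluster_mutation_rate + 1))
                cdr3 = _mutate(seed, n_edits, rng)
            else:
                cdr3 = _random_cdr3(rng, lo, hi)
            locus = "IGH"
        else:
            locus = "IGK" if rng.random() < self._kappa_p else "IGL"
            cdr3 = _random_cdr3(rng, max(5, lo - 3), max(7, hi - 5))
        v = _V_GENES[locus][int(rng.integers(0, len(_V_GENES[locus])))]
        j = _J_GENES[locus][int(rng.integers(0, len(_J_GENES[locus])))]
        return locus, v, j, cdr3

    def draw(self, kind: str) -> tuple[str, str, str, str]:
        cfg, rng = self.config, self.rng
        if rng.random() < cfg.tissue_overlap:
            pool = self.shared_heavy if kind == "IGH" else self.shared_light
            return pool[int(rng.integers(0, len(pool)))]
        return self._fresh(kind)


def _sample_kappa_prob(config: SimConfig, rng: np.random.Generator) -> float:
    if config.kappa_prob in (0.0, 1.0) or config.kappa_prob_sd == 0:
        return config.kappa_prob
    p = rng.normal(config.kappa_prob, config.kappa_prob_sd)
    return float(np.clip(p, 0.02, 0.98))


def simulate_repertoires(config: SimConfig) -> list[RepertoireSample]:
    """Generate one cohort of repertoire samples.

    Patients ``P01..Pn``; the first ``round(pss_fraction * n_patients)``
    are pSS, the rest controls. One sample per (patient, tissue).
    Deterministic: the same config (incl. seed) yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cdr3_length_range
    seed_len_lo = max(lo, min(hi, 14))
    seeds = [_random_cdr3(rng, seed_len_lo, seed_len_lo) for _ in range(config.n_cluster_seeds)]

    n_pss = int(round(config.pss_fraction * config.n_patients))
    samples: list[RepertoireSample] = []
    for ipat in range(config.n_patients):
        patient = f"{config.patient_prefix}{ipat + 1:02d}"
        group = "pSS" if ipat < n_pss else "control"
        factory = _ClonotypeFactory(config, rng, seeds, _sample_kappa_prob(config, rng))
        for tissue in config.tissues:
            sid = f"{patient}_{tissue}"
            if config.mode == "bulk":
                samples.append(_bulk_sample(config, rng, factory, sid, patient, tissue, group))
            else:
                samples.append(_sc_sample(config, rng, factory, sid, patient, tissue, group))
    _couple_essdai(config, rng, samples)
    return samples


def _bulk_sample(config, rng, factory, sid, patient, tissue, group) -> RepertoireSample:
    names, probs = _profile_for(config, tissue, "bulk", group)
    chains: list[ChainRecord] = []
    iso_idx = rng.choice(len(names), size=config.n_chains, p=probs)
    for i in range(config.n_chains):
        locus, v, j, cdr3 = factory.draw("IGH")
        chains.append(
            ChainRecord(
                sequence_id=f"{sid}_H{i:05d}",
                sample_id=sid,
                locus="IGH",
                v_gene=v,
                j_gene=j,
                c_gene=names[int(iso_idx[i])],
                cdr3_nt=_nt_for(cdr3),
                cdr3_aa=cdr3,
                read_count=_clone_size(rng, config.clone_size_law),
            )
        )
    for i in range(config.n_chains):
        locus, v, j, cdr3 = factory.draw("light")
        chains.append(
            ChainRecord(
                sequence_id=f"{sid}_L{i:05d}",
                sample_id=sid,
                locus=locus,
                v_gene=v,
                j_gene=j,
                c_gene=_LIGHT_C[locus],
                cdr3_nt=_nt_for(cdr3),
                cdr3_aa=cdr3,
                read_count=_clone_size(rng, config.clone_size_law),
            )
        )
    return RepertoireSample(sample_id=sid, patient=patient, tissue=tissue, group=group, chains=chains)


def _sc_sample(config, rng, factory, sid, patient, tissue, group) -> RepertoireSample:
    ct_profile = config.cell_type_profile[_tissue_class(tissue)]
    ct_names = list(ct_profile)
    ct_probs = np.array([ct_profile[n] for n in ct_names], dtype=float)
    ct_probs /= ct_probs.sum()

    cells: list[BCell] = []
    iclone = 0
    while len(cells) < config.n_cells:
        size = min(_clone_size(rng, config.clone_size_law), config.n_cells - len(cells))
        _, hv, hj, hcdr3 = factory.draw("IGH")
        llocus, lv, lj, lcdr3 = factory.draw("light")
        cell_type = ct_names[int(rng.choice(len(ct_names), p=ct_probs))]
        names, probs = _profile_for(config, tissue, cell_type, group)
        c_gene = names[int(rng.choice(len(names), p=probs))]
        clone_id = f"{sid}_c{iclone:04d}"
        for k in range(size):
            barcode = f"{sid}-{len(cells):05d}"
            heavy = ChainRecord(
                sequence_id=f"{barcode}_IGH",
                sample_id=sid,
                locus="IGH",
                v_gene=hv,
                j_gene=hj,
                c_gene=c_gene,
                cdr3_nt=_nt_for(hcdr3),
                cdr3_aa=hcdr3,
            )
            light = ChainRecord(
                sequence_id=f"{barcode}_{llocus}",
                sample_id=sid,
                locus=llocus,
                v_gene=lv,
                j_gene=lj,
                c_gene=_LIGHT_C[llocus],
                cdr3_nt=_nt_for(lcdr3),
                cdr3_aa=lcdr3,
            )
            cells.append(
                BCell(
                    barcode=barcode,
                    patient=patient,
                    tissue=tissue,
                    cell_type=cell_type,
                    heavy=heavy,
                    light=light,
                    clone_id=clone_id,
                    clone_size=size,
                )
            )
        iclone += 1
    return RepertoireSample(sample_id=sid, patient=patient, tissue=tissue, group=group, cells=cells)


def _realized_kl_ratio(sample: RepertoireSample) -> float:
    kappa = sum(c.read_count for c in sample.iter_chains() if c.locus == "IGK")
    lam = sum(c.read_count for c in sample.iter_chains() if c.locus == "IGL")
    if lam == 0:
        return float("nan")
    return kappa / lam


def _couple_essdai(config: SimConfig, rng: np.random.Generator, samples: list[RepertoireSample]) -> None:
    pss = [s for s in samples if s.group == "pSS"]
    if not pss:
        return
    ratios = np.array([_realized_kl_ratio(s) for s in pss])
    finite = np.isfinite(ratios)
    noise_sd = config.essdai_noise_sd
    if noise_sd is None:
        r = config.essdai_target_r
        if r is None or config.essdai_slope == 0:
            noise_sd = 1.0
        else:
            spread = float(np.std(ratios[finite])) if finite.sum() >= 2 else 0.0
            if spread == 0.0:
                noise_sd = 1.0
            else:
                noise_sd = abs(config.essdai_slope) * spread * np.sqrt(1.0 / r**2 - 1.0)
    for sample, ratio in zip(pss, ratios):
        if not np.isfinite(ratio):
            sample.essdai = None
            continue
        value = config.essdai_slope * ratio + config.essdai_intercept + rng.normal(0.0, noise_sd)
        sample.essdai = float(max(0.0, value))


def enriched_membership(prob: float, enrichment: float) -> float:
    """Case-group cluster membership: prob * enrichment, capped at 1."""
    return min(1.0, prob * enrichment)


def plant_case_control(
    config: SimConfig, cluster_enrichment: float
) -> tuple[list[RepertoireSample], list[RepertoireSample]]:
    """Simulate a case cohort with enriched planted-cluster membership and
    a background control cohort.

    The case group's cluster_membership_prob is multiplied by
    ``cluster_enrichment`` (capped at 1); cases are labelled pSS, controls
    control. Seeds for the two cohorts derive deterministically from
    ``config.seed``.
    """
    if cluster_enrichment <= 1.0:
        raise ConfigError("cluster_enrichment must be > 1")
    case_p = enriched_membership(config.cluster_membership_prob, cluster_enrichment)
    case_cfg = dataclasses.replace(
        config,
        cluster_membership_prob=case_p,
        pss_fraction=1.0,
        patient_prefix="S",
        seed=(config.seed * 2 + 1) % (2**31),
    )
    ctrl_cfg = dataclasses.replace(
        config,
        pss_fraction=0.0,
        patient_prefix="C",
        seed=(config.seed * 2 + 2) % (2**31),
    )
    return simulate_repertoires(case_cfg), simulate_repertoires(ctrl_cfg)


# ---------------------------------------------------------------------------
# emitters matching the formats the readers consume


def write_trust4_report(sample: RepertoireSample, path) -> None:
    """Write a bulk sample as a TRUST4-style report TSV."""
    total = sum(c.read_count for c in sample.chains) or 1
    rows = [
        {
            "#count": c.read_count,
            "frequency": round(c.read_count / total, 6),
            "CDR3nt": c.cdr3_nt,
            "CDR3aa": c.cdr3_aa,
            "V": c.v_gene,
            "D": ".",
            "J": c.j_gene,
            "C": c.c_gene,
            "cid": c.sequence_id,
            "cid_full_length": 1,
        }
        for c in sample.chains
    ]
    cols = ["#count", "frequency", "CDR3nt", "CDR3aa", "V", "D", "J", "C", "cid", "cid_full_length"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_contigs_csv(cells: Sequence[BCell], path) -> None:
    """Write single-cell B cells as a 10X-style contig annotation CSV."""
    rows = []
    for cell in cells:
        for chain in (cell.heavy, cell.light):
            rows.append(
                {
                    "barcode": cell.barcode,
                    "is_cell": "True",
                    "contig_id": chain.sequence_id,
                    "chain": chain.locus,
                    "v_gene": chain.v_gene,
                    "d_gene": "None",
                    "j_gene": chain.j_gene,
                    "c_gene": chain.c_gene,
                    "cdr3": chain.cdr3_aa,
                    "cdr3_nt": chain.cdr3_nt,
                    "productive": "True",
                    "reads": chain.read_count,
                    "umis": chain.read_count,
                    "raw_clonotype_id": cell.clone_id,
                    "cell_type": cell.cell_type,
                    "sample_id": chain.sample_id,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_metadata(samples: Sequence[RepertoireSample], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "patient": s.patient,
            "tissue": s.tissue,
            "group": s.group,
            "essdai": "" if s.essdai is None else s.essdai,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
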