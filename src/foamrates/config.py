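"""Study configuration for the synthetic data generator.

Defaults encode the study design being emulated: a foam-gland (FG) /
testis RNA-seq experiment with three photoperiod/hormone treatments (LD,
SD, SD+T), six males per treatment (FG sampled in all three, testis in LD
and SD only), quail-chicken ortholog pairs diverging at class-specific
omega, a secreted foam-protein subset with peptide evidence, planted gene
ages, and per-gene polymorphism.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

#: study classes controlling every planted property of a gene
STUDY_CLASSES = [
    "fp",                # FG-enriched, induced in both FG contrasts, in foam
    "fg_induced",        # FG-enriched, induced in both FG contrasts, not in foam
    "fg_not_induced",    # FG-enriched, flat
    "testis_induced",    # testis-enriched, induced in testis LD vs SD
    "testis_not_induced",# testis-enriched, flat
    "both_up",           # testis-enriched but induced in BOTH tissues (dropped in scheme A)
    "fg_expressed",      # expressed in FG, not enriched anywhere
    "other",             # not expressed in FG
]

DEFAULT_CLASS_FRACTIONS = {
    "fp": 0.02,
    "fg_induced": 0.035,
    "fg_not_induced": 0.05,
    "testis_induced": 0.18,
    "testis_not_induced": 0.05,
    "both_up": 0.015,
    "fg_expressed": 0.43,
    "other": 0.22,
}

#: planted dN/dS per class: foam proteins strongly conserved, breeding-condition
#: testis genes fast, matching the contrast the study is built to expose
DEFAULT_OMEGA = {
    "fp": 0.13,
    "fg_induced": 0.15,
    "fg_not_induced": 0.20,
    "testis_induced": 0.50,
    "testis_not_induced": 0.20,
    "both_up": 0.25,
    "fg_expressed": 0.145,
    "other": 0.245,
}

#: probability a gene has a detectable 1:1 ortholog in the reference genome
DEFAULT_ORTHOLOG_FRACTION = {
    "fp": 0.87,
    "fg_induced": 0.43,
    "fg_not_induced": 0.33,
    "testis_induced": 0.40,
    "testis_not_induced": 0.24,
    "both_up": 0.40,
    "fg_expressed": 0.50,
    "other": 0.24,
}

#: per-site population mutation rate by class (breeding-condition-induced
#: genes slightly more polymorphic)
DEFAULT_THETA = {
    "fp": 0.0027,
    "fg_induced": 0.0027,
    "fg_not_induced": 0.0024,
    "testis_induced": 0.0027,
    "testis_not_induced": 0.0024,
    "both_up": 0.0027,
    "fg_expressed": 0.0027,
    "other": 0.0025,
}

ORIGIN_CLASSES = ["Aves", "Vertebrate", "Animal", "Eukaryote", "Bacteria+Archaea"]

#: gene-age distribution by class (order as ORIGIN_CLASSES); foam proteins
#: skew ancient, not-induced structural genes skew vertebrate
DEFAULT_AGE_WEIGHTS = {
    "fp": [0.05, 0.15, 0.20, 0.25, 0.35],
    "fg_induced": [0.25, 0.35, 0.20, 0.15, 0.05],
    "fg_not_induced": [0.15, 0.45, 0.20, 0.15, 0.05],
    "testis_induced": [0.15, 0.25, 0.20, 0.30, 0.10],
    "testis_not_induced": [0.15, 0.45, 0.20, 0.15, 0.05],
    "both_up": [0.20, 0.35, 0.20, 0.20, 0.05],
    "fg_expressed": [0.20, 0.35, 0.20, 0.20, 0.05],
    "other": [0.20, 0.35, 0.20, 0.20, 0.05],
}

DEFAULT_TAXA = {
    "quail": "Aves",
    "chicken": "Aves",
    "mouse": "Vertebrate",
    "fly": "Animal",
    "yeast": "Eukaryote",
    "ecoli": "Bacteria+Archaea",
}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the study conditions as
    defaults. One integer seed drives every stream of randomness."""

    n_genes: int = 3000
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    omega_by_class: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OMEGA)
    )
    ortholog_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORTHOLOG_FRACTION)
    )
    theta_by_class: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THETA)
    )
    age_weights: Mapping[str, list] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_AGE_WEIGHTS.items()}
    )
    taxa: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_TAXA))
    focal_taxon: str = "quail"
    target_ds: float = 0.15      # expected synonymous divergence per pair
    n_males: int = 6             # biological replicates per treatment
    treatments: tuple = ("LD", "SD", "SD+T")
    theta: float = 0.0025        # fallback when a class is missing above
    n_haplotypes: int = 24       # 12 diploid males
    gene_length_bp: int = 1500   # contig/span length for the variant layer
    cds_codons_range: tuple = (100, 200)
    library_size_range: tuple = (800_000, 1_600_000)
    nb_dispersion: float = 0.1
    induced_log2fc: float = 2.0
    z_fraction: float = 0.10     # genes on the Z chromosome
    seed: int = 42

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, not 1")
        if any(w <= 0 for w in self.omega_by_class.values()):
            raise ValueError("all omega must be > 0")
        if self.n_haplotypes < 2:
            raise ValueError("need >= 2 haplotypes")
        if self.nb_dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> SimConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("treatments", "cds_codons_range", "library_size_range"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SimConfig(**data)


def save_config(cfg: SimConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
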