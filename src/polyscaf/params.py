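"""Parameter containers for the simulator and the scaffolding pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ParameterError


@dataclass
class SimParams:
    """Generative parameters of the synthetic allopolyploid genome.

    Defaults describe the package's reference scenario: a hexaploid (K=3)
    with three 1-Mb chromosomes per subgenome, whose subgenomes split from a
    common ancestor at distinct per-site divergences (1%, 3%, 6%), a diploid
    relative 0.5% diverged from that ancestor, contigs of mean 30 kb, and
    2e5 Hi-C contact pairs with 1/s distance decay, 2% inter-chromosomal
    background and 5% homoeologous mis-mapping.
    """

    n_subgenomes: int = 3
    n_chromosomes_per_subgenome: int = 3
    chromosome_length: int = 1_000_000
    gc_fraction: float = 0.44
    diploid_divergence: float = 0.005
    subgenome_divergences: tuple[float, ...] = (0.01, 0.03, 0.06)
    mean_contig_length: int = 30_000
    min_contig_length: int = 5_000
    n_contact_pairs: int = 200_000
    decay_exponent: float = 1.0
    inter_chromosome_background: float = 0.02
    mismap_fraction: float = 0.05
    telomere_copies: int = 100
    centromere_unit: int = 155
    centromere_copies: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.subgenome_divergences = tuple(self.subgenome_divergences)
        self.validate()

    def validate(self) -> None:
        p = self
        if p.n_subgenomes < 1:
            raise ParameterError("n_subgenomes must be >= 1")
        if p.n_chromosomes_per_subgenome < 1:
            raise ParameterError("n_chromosomes_per_subgenome must be >= 1")
        if p.chromosome_length < 1:
            raise ParameterError("chromosome_length must be positive")
        if not 0.0 < p.gc_fraction < 1.0:
            raise ParameterError("gc_fraction must lie in (0, 1)")
        if not 0.0 <= p.diploid_divergence < 1.0:
            raise ParameterError("diploid_divergence must lie in [0, 1)")
        if len(p.subgenome_divergences) != p.n_subgenomes:
            raise ParameterError(
                f"expected {p.n_subgenomes} subgenome divergences, "
                f"got {len(p.subgenome_divergences)}"
            )
        for d in p.subgenome_divergences:
            if not 0.0 <= d < 1.0:
                raise ParameterError("subgenome divergences must lie in [0, 1)")
        if len(set(p.subgenome_divergences)) != len(p.subgenome_divergences):
            raise ParameterError("subgenome divergences must be pairwise distinct")
        if not p.min_contig_length <= p.mean_contig_length <= p.chromosome_length:
            raise ParameterError(
                "require min_contig_length <= mean_contig_length <= chromosome_length"
            )
        if p.n_contact_pairs <= 0:
            raise ParameterError("n_contact_pairs must be positive")
        if p.decay_exponent <= 0:
            raise ParameterError("decay_exponent must be > 0")
        if not 0.0 <= p.inter_chromosome_background < 1.0:
            raise ParameterError("inter_chromosome_background must lie in [0, 1)")
        if not 0.0 <= p.mismap_fraction < 1.0:
            raise ParameterError("mismap_fraction must lie in [0, 1)")
        if p.telomere_copies < 0 or p.centromere_copies < 0:
            raise ParameterError("feature copy numbers must be >= 0")
        if p.centromere_unit < 2:
            raise ParameterError("centromere_unit must be >= 2")
        if not 0 <= p.seed < 2**31:
            raise ParameterError("seed must lie in [0, 2^31)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subgenome_divergences"] = list(self.subgenome_divergences)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)


@dataclass
class PipelineConfig:
    """Tunable parameters of the assignment / chromosome-building pipeline.

    k_depth=100 is the diploid depth-signal k-mer size; anchor_k=21 the
    synteny-anchor size; k_val=13 and enrichment_ratio=10 govern the
    subgenome-specific k-mer validation.
    """

    n_subgenomes: int = 3
    k_depth: int = 100
    anchor_k: int = 21
    k_val: int = 13
    enrichment_ratio: float = 10.0
    ambiguity_margin: float = 0.1
    min_anchors: int = 8
    max_anchor_occurrences: int | None = None  # default: n_subgenomes
    max_anchors_per_pair: int = 2000
    reassign_margin: float = 2.0
    max_rounds: int = 5
    reassign_unassigned: bool = True
    refine_passes: int = 3
    gap_size: int = 100
    min_vote: float = 0.6
    min_orient_anchors: int = 3
    telomere_monomer: str = "AAACCCT"
    telomere_end_window: int = 5_000
    telomere_min_copies: int = 10
    centromere_unit: int = 155
    centromere_min_copies: int = 10
    centromere_min_identity: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_anchor_occurrences is None:
            self.max_anchor_occurrences = self.n_subgenomes
        self.validate()

    def validate(self) -> None:
        for name in ("n_subgenomes", "k_depth", "anchor_k", "k_val", "max_rounds",
                     "gap_size", "min_anchors"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive integer")
        if self.refine_passes < 0:
            raise ParameterError("refine_passes must be >= 0")
        if self.enrichment_ratio <= 1:
            raise ParameterError("enrichment_ratio must be > 1")
        if self.anchor_k >= self.k_depth:
            raise ParameterError("anchor_k must be smaller than k_depth")
        if not 0.0 < self.min_vote <= 1.0:
            raise ParameterError("min_vote must lie in (0, 1]")
        if self.reassign_margin < 1.0:
            raise ParameterError("reassign_margin must be >= 1")
        if not 0 <= self.seed < 2**31:
            raise ParameterError("seed must lie in [0, 2^31)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)
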