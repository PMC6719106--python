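"""Pipeline-wide configuration: every numeric threshold used by any stage.

All cut-offs live here so that a run is fully described by one object.
Boundary semantics (strict vs inclusive) are part of the contract and are
asserted by the boundary test suite:

* transcript length must exceed ``min_length_nt`` (strict ``>``),
* exon count is inclusive at ``min_exons`` (``>=``),
* homology E-values must fall strictly below the threshold,
* phastCons-style conservation scores must strictly exceed ``phastcons_min``,
* co-expression targeting requires ``|r|`` strictly above ``coexpr_abs_r_min``,
* hub calling requires degree strictly above ``hub_min_degree``,
* the cis window is inclusive at ``cis_window_bp``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

__all__ = ["PipelineConfig", "STAGE_ORDER", "EARLY_STAGES", "LATE_STAGES"]

#: Developmental stages in temporal order: five fetal ages (days post
#: conception) followed by 1 and 90 days after birth.
STAGE_ORDER: tuple[str, ...] = ("F45", "F65", "F90", "F120", "F135", "B1", "B90")

#: Stage subsets defining the early / late temporal classes of modules.
EARLY_STAGES: frozenset[str] = frozenset({"F45", "F65", "F90"})
LATE_STAGES: frozenset[str] = frozenset({"F135", "B1", "B90"})


@dataclass(frozen=True)
class PipelineConfig:
    """Numeric thresholds for every pipeline stage (defaults as published)."""

    min_length_nt: int = 200          # lncRNA definition: length > 200 nt (strict)
    min_exons: int = 2                # multi-exonic: >= 2 exons (inclusive)
    evalue_loose: float = 1e-3        # loose homology threshold (strict <)
    evalue_strict: float = 1e-10      # strict homology threshold (strict <)
    phastcons_min: float = 0.8        # conservation score cut (strict >)
    de_alpha: float = 0.05            # differential-expression p cut
    module_trait_r_min: float = 0.6   # module-stage correlation cut (strict >)
    module_trait_alpha: float = 0.05  # module-stage p cut
    coexpr_abs_r_min: float = 0.95    # co-expression targeting |r| cut (strict >)
    fc_min: float = 2.0               # linear fold-change cut: |log2FC| >= log2(fc_min)
    hub_min_degree: int = 10          # hub lncRNA: degree > 10 (strict)
    cis_window_bp: int = 100_000      # cis search window (inclusive)
    detection_fpkm_min: float = 0.1   # stage detection: mean FPKM > this
    soft_power_max: int = 20          # candidate soft-threshold powers 1..max
    scale_free_fit_target: float = 0.8
    soft_power_fallback: int = 12
    min_module_size: int = 20
    cut_height_fraction: float = 0.995  # static tree cut at fraction of max height
    kme_min: float = 0.7              # module-membership cleanup: r(feature, eigengene)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"config field {f.name} must be positive, got {v!r}")
        for name in ("de_alpha", "module_trait_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
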