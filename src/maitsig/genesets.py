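"""Built-in gene sets and the YAML-backed gene-set catalog.

The defaults are the curated immune gene lists the pipeline scores:
a T-cell activation/function module, an immune checkpoint / dysfunction
(exhaustion) module, the 11-gene MAIT signature, pan-T-cell markers
(CD3 complex) and NK-cell markers used to audit signature specificity
in bulk cohorts.
"""

from __future__ import annotations

from typing import Mapping

import yaml

from .datatypes import ConfigError, SignatureDefinition

ACTIVATION_GENES = (
    "CD69", "CD38", "HLA-DRA", "IL2RA", "TNFRSF9",
    "TNF", "GNLY", "IFNG", "GZMB", "GZMA", "GZMH",
)
EXHAUSTION_GENES = (
    "PDCD1", "CTLA4", "TIGIT", "CXCL13", "ENTPD1", "LAG3", "ITGAE", "LAYN",
)
MAIT_SIGNATURE_GENES = (
    "SLC4A10", "KLRB1", "ME1", "TMIGD2", "IL23R",
    "NCR3", "LST1", "COLQ", "RORC", "ZBTB16", "TLE1",
)
PAN_T_GENES = ("CD3D", "CD3E", "CD3G")
NK_GENES = ("XCL2", "PRF1", "KLRF1", "KLRD1", "IL2RB", "CD244", "CD160")


class GeneSetCatalog:
    """Named gene lists: the built-in defaults plus user-defined sets."""

    def __init__(self, extra: Mapping[str, list[str]] | None = None) -> None:
        self._sets: dict[str, SignatureDefinition] = {
            "activation_genes": SignatureDefinition(
                "activation_genes", list(ACTIVATION_GENES), "paper_default"
            ),
            "exhaustion_genes": SignatureDefinition(
                "exhaustion_genes", list(EXHAUSTION_GENES), "paper_default"
            ),
            "mait_signature": SignatureDefinition(
                "mait_signature", list(MAIT_SIGNATURE_GENES), "paper_default"
            ),
            "pan_t_genes": SignatureDefinition(
                "pan_t_genes", list(PAN_T_GENES), "paper_default"
            ),
            "nk_genes": SignatureDefinition(
                "nk_genes", list(NK_GENES), "paper_default"
            ),
        }
        if extra:
            for name, genes in extra.items():
                self.add(SignatureDefinition(name, list(genes), "user"))

    def add(self, signature: SignatureDefinition) -> None:
        self._sets[signature.name] = signature

    def __getitem__(self, name: str) -> SignatureDefinition:
        try:
            return self._sets[name]
        except KeyError:
            raise ConfigError(
                f"unknown gene set '{name}'; available: {sorted(self._sets)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def names(self) -> list[str]:
        return sorted(self._sets)

    @classmethod
    def from_yaml(cls, path) -> "GeneSetCatalog":
        """Load user gene sets (mapping name -> list of symbols) on top of defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of set-name -> gene list")
        return cls(extra=data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {name: list(sig.genes) for name, sig in self._sets.items()},
                fh,
                sort_keys=True,
            )
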