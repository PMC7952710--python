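"""End-to-end discovery pipeline: table -> quantize -> catalog -> SR ->
disentangle -> pattern groups -> patterns -> knowledge base."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from . import __version__
from .ava_statistics import AVCatalog, SRMatrix, build_av_catalog, build_sr_matrix
from .config import RunConfig
from .disentanglement import (
    DisentangledSpace,
    DSUCode,
    DSUnit,
    decompose,
    enumerate_units,
    select_spaces,
)
from .knowledge_base import PDDKB, build_kb, table_digest
from .pattern_mining import Pattern, associate_all, grow_patterns
from .tabular_io import QuantizationScheme, RelationalTable, quantize

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryResult:
    """Everything one discovery run produced, for inspection and export."""

    table: RelationalTable  # quantized working table
    scheme: QuantizationScheme
    catalog: AVCatalog
    sr: SRMatrix
    spaces: list[DisentangledSpace]
    retained: list[DisentangledSpace]
    units: list[DSUnit]
    patterns_by_unit: dict
    kb: PDDKB

    @property
    def all_patterns(self) -> list[Pattern]:
        return [p for pats in self.patterns_by_unit.values() for p in pats]


def run_discovery(
    table: RelationalTable,
    config: Optional[RunConfig] = None,
    scheme: Optional[QuantizationScheme] = None,
) -> DiscoveryResult:
    """Run the full discovery pipeline on a relational table.

    Class labels, when present, never enter the statistics: they are only
    placed back as references when patterns are associated to classes.  A
    pre-fit quantization scheme can be supplied (train-fit, test-apply);
    otherwise one is fit on the table itself.
    """
    config = config or RunConfig()
    if scheme is not None:
        work = scheme.apply(table)
    else:
        work, scheme = quantize(
            table, bins=config.bins, method=config.quantization_method
        )
    catalog = build_av_catalog(work)
    logger.info(
        "catalog: %d AVs over %d attributes, N=%d",
        len(catalog),
        catalog.n_attributes_present,
        catalog.N,
    )
    sr = build_sr_matrix(catalog)
    spaces = decompose(sr)
    retained = select_spaces(spaces, config.threshold)
    units = enumerate_units(retained, config.threshold)
    patterns_by_unit: dict[DSUCode, list[Pattern]] = {}
    n_pat = 0
    for unit in units:
        res = grow_patterns(
            unit,
            catalog,
            threshold=config.threshold,
            min_occurrence=config.min_occurrence,
            max_order=config.max_order,
        )
        pats = res.patterns
        if work.labels is not None:
            labels = {
                e: work.labels.at[e]
                for e in work.entity_ids
                if work.labels.at[e] is not None
            }
            pats = associate_all(pats, labels)
        patterns_by_unit[unit.code] = pats
        n_pat += len(pats)
    logger.info("discovered %d patterns across %d units", n_pat, len(units))
    metadata = {
        "config": config.to_dict(),
        "quantization": scheme.to_dict(),
        "catalog_digest": table_digest(work),
        "n_avs": len(catalog),
        "retained_ds": [s.ordinal for s in retained],
        "version": __version__,
    }
    kb = build_kb(units, patterns_by_unit, work, metadata)
    return DiscoveryResult(
        table=work,
        scheme=scheme,
        catalog=catalog,
        sr=sr,
        spaces=spaces,
        retained=retained,
        units=units,
        patterns_by_unit=patterns_by_unit,
        kb=kb,
    )
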