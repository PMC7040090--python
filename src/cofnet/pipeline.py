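"""End-to-end wiring: benchmark each source, select parameters, integrate.

Thin convenience layer over :mod:`cofnet.gold` and :mod:`cofnet.integration`
used by the CLI, the examples and the acceptance checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .gold import (
    AdmissionResult,
    BinnedLLS,
    CalibrationCurve,
    GoldStandard,
    bin_and_score,
    calibrate_evidence,
    filter_admissible,
    fit_calibration,
)
from .integration import (
    DEFAULT_D_GRID,
    DEFAULT_T_GRID,
    IntegrationParams,
    integrate,
    select_params,
)
from .model import EvidenceTable, WeightedNetwork

logger = logging.getLogger(__name__)


@dataclass
class BenchmarkResult:
    """One source's journey from raw scores to admitted LLS links."""

    source_code: str
    binned: BinnedLLS
    curve: CalibrationCurve
    calibrated: EvidenceTable
    admission: AdmissionResult


def benchmark_source(
    table: EvidenceTable,
    gs: GoldStandard,
    bin_size: int = 1000,
    min_links: int = 2000,
) -> BenchmarkResult:
    """Bin, fit the sigmoid calibration, calibrate every pair, apply the
    better-than-random admission filter."""
    binned = bin_and_score(table, gs, bin_size=bin_size)
    curve = fit_calibration(binned)
    calibrated = calibrate_evidence(table, curve)
    admission = filter_admissible(calibrated, min_links=min_links)
    return BenchmarkResult(table.source_code, binned, curve, calibrated, admission)


@dataclass
class BuildResult:
    network: WeightedNetwork
    params: IntegrationParams
    benchmarks: List[BenchmarkResult]
    admitted_sources: List[str]
    rejected_sources: List[str]


def build_network(
    tables: Sequence[EvidenceTable],
    gs: GoldStandard,
    bin_size: int = 1000,
    min_links: int = 2000,
    params: Optional[IntegrationParams] = None,
    D_grid: Sequence[float] = DEFAULT_D_GRID,
    T_grid: Sequence[float] = DEFAULT_T_GRID,
) -> BuildResult:
    """Benchmark every source against the gold standard and integrate the
    admitted ones into one network.

    When ``params`` is omitted, D and T are grid-searched on the admitted
    evidence against the gold standard's precision–recall curve.
    """
    benchmarks = [
        benchmark_source(t, gs, bin_size=bin_size, min_links=min_links)
        for t in tables
    ]
    admitted = [b.admission.table for b in benchmarks if b.admission.admitted]
    rejected = [b.source_code for b in benchmarks if not b.admission.admitted]
    if not admitted:
        raise ValueError("no evidence source passed the admission filter")
    if rejected:
        logger.info("rejected sources: %s", rejected)
    if params is None:
        params = select_params(admitted, gs, D_grid=D_grid, T_grid=T_grid)
    net = integrate(admitted, params)
    return BuildResult(
        net, params, benchmarks, [t.source_code for t in admitted], rejected
    )
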