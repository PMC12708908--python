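"""End-to-end feature extraction: records -> feature table."""
from __future__ import annotations

import logging

import pandas as pd

from . import signal_prep
from .feature_table import FeatureTable, table_from_records
from .individual_features import individual_features
from .synchrony import DEFAULT_GRID_HZ, synchrony_features_for_interval
from .types import DyadRecord

logger = logging.getLogger(__name__)


def extract_feature_table(records: list[DyadRecord],
                          rate_grid_hz: float = DEFAULT_GRID_HZ,
                          apply_filters: bool = True) -> FeatureTable:
    """Run peak/SCR detection and all feature computations for a cohort.

    Produces one individual-feature row per (dyad, interval, participant)
    and one synchrony row per (dyad, interval) over all 12 intervals
    (baselines included, so baseline normalization is possible downstream).
    """
    ind_rows, sync_rows = [], []
    for rec in records:
        for interval_index in range(rec.n_intervals):
            prepared = {}
            for p in (1, 2):
                prep = signal_prep.prepare_interval(
                    rec.interval(p, interval_index, "ecg"),
                    rec.interval(p, interval_index, "eda"),
                    rec.interval(p, interval_index, "resp"),
                    rec.interval(p, interval_index, "temp"),
                    rate_grid_hz=rate_grid_hz, apply_filters=apply_filters)
                prepared[p] = prep
                row = {"dyad_id": rec.dyad_id, "interval_index": interval_index,
                       "participant": p}
                row.update(individual_features(prep))
                ind_rows.append(row)
            srow = {"dyad_id": rec.dyad_id, "interval_index": interval_index}
            srow.update(synchrony_features_for_interval(
                prepared[1], prepared[2], grid_rate=rate_grid_hz))
            sync_rows.append(srow)
        logger.debug("extracted features for dyad %s", rec.dyad_id)
    return table_from_records(records, pd.DataFrame(ind_rows),
                              pd.DataFrame(sync_rows))
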