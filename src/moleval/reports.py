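"""Report rendering: JSON and CSV serialization with full provenance.

Every report embeds the run configuration, table label, and package
version, so a result file is interpretable without the shell history that
produced it.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence, Union

from .metrics import MetricReport

CSV_COLUMNS = ["metric", "value", "std", "n_molecules", "n_splits", "config"]


def _provenance(config: dict) -> dict:
    from . import __version__
    return {"package": "moleval", "version": __version__, "config": config}


def write_metric_reports(reports: Sequence[MetricReport], config: dict,
                         json_path: Union[str, Path, None] = None,
                         csv_path: Union[str, Path, None] = None) -> dict:
    payload = _provenance(config)
    payload["metrics"] = [r.to_dict() for r in reports]
    if json_path:
        Path(json_path).write_text(json.dumps(payload, indent=1) + "\n")
    if csv_path:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            for r in reports:
                d = r.to_dict()
                d["config"] = json.dumps({**config, **d["config"]},
                                         sort_keys=True)
                writer.writerow({k: d[k] for k in CSV_COLUMNS})
    return payload


def write_json(obj: dict, config: dict, path: Union[str, Path]) -> dict:
    payload = _provenance(config)
    payload.update(obj)
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
    return payload
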