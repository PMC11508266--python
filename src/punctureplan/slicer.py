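"""Export of planned routes as 3D Slicer markups files (.mrk.json).

Each route becomes a Line markup with two control points (target, skin
entry); all entry points are additionally collected into one Fiducial
markup.  Volume-local mm coordinates are treated as LPS (the DICOM patient
frame) and converted to RAS — Slicer's internal frame — by negating x and y.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

from .ranking import RankedRoute
from .volume import logger

_SCHEMA = ("https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/"
           "Markups/Resources/Schema/markups-schema-v1.0.3.json")


def lps_to_ras(point: Sequence[float]) -> tuple[float, float, float]:
    return (-float(point[0]), -float(point[1]), float(point[2]))


def _control_point(cp_id: int, label: str, position_ras: Sequence[float]) -> dict:
    return {
        "id": str(cp_id),
        "label": label,
        "position": [float(c) for c in position_ras],
        "orientation": [-1.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0, 1.0],
        "selected": True,
        "locked": False,
        "visibility": True,
        "positionStatus": "defined",
    }


def _markup(markup_type: str, control_points: list[dict]) -> dict:
    return {
        "type": markup_type,
        "coordinateSystem": "RAS",
        "coordinateUnits": "mm",
        "locked": False,
        "labelFormat": "%N-%d",
        "controlPoints": control_points,
    }


def export_slicer_markups(routes: Sequence[RankedRoute], out_dir: Union[str, Path],
                          prefix: str = "route") -> list[Path]:
    """Write one Line file per route plus a Fiducial file of all entries.

    Returns the written paths (empty list, with a warning, for no routes).
    """
    out_dir = Path(out_dir)
    if not routes:
        logger.warning("no routes to export; skipping markups")
        return []
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    entry_points: list[dict] = []
    for rr in routes:
        r = rr.route
        target_ras = lps_to_ras(r.target)
        entry_ras = lps_to_ras(r.entry_point)
        line = _markup("Line", [
            _control_point(1, "target", target_ras),
            _control_point(2, f"entry rank {rr.rank}", entry_ras),
        ])
        path = out_dir / f"{prefix}_{rr.rank:02d}.mrk.json"
        path.write_text(json.dumps({"@schema": _SCHEMA, "markups": [line]}, indent=2))
        written.append(path)
        entry_points.append(_control_point(rr.rank, f"entry rank {rr.rank}", entry_ras))
    fid_path = out_dir / f"{prefix}_entry_points.mrk.json"
    fid = _markup("Fiducial", entry_points)
    fid_path.write_text(json.dumps({"@schema": _SCHEMA, "markups": [fid]}, indent=2))
    written.append(fid_path)
    return written


def read_markup_positions(path: Union[str, Path]) -> list[tuple[float, float, float]]:
    """Parse control-point RAS positions back from a markups file."""
    doc = json.loads(Path(path).read_text())
    out = []
    for markup in doc["markups"]:
        for cp in markup["controlPoints"]:
            out.append(tuple(float(c) for c in cp["position"]))
    return out
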