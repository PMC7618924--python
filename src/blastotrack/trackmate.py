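"""TrackMate-style XML export/import of lineage forests.

A minimal but schema-faithful subset of the TrackMate model file: one
``Spot`` per (frame, label) node with physical coordinates in μm and a
radius from the volume-equivalent sphere, one ``Edge`` per link, ``Track``
elements grouping weakly connected components.  The bundled reader
round-trips the forest exactly, so automated results can be curated in
Fiji's TrackMate and read back.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
from lxml import etree

from .core import DataFormatError
from .lineage import LineageForest


def _spot_id(frame: int, label: int, stride: int) -> int:
    return frame * stride + label


def export_trackmate(forest: LineageForest, records=None,
                     spacing=(1.0, 1.0, 1.0), path: str | Path | None = None
                     ) -> etree._ElementTree:
    """Serialize a lineage forest as TrackMate-style XML.

    ``records`` maps ``(frame, label)`` to a dict with at least ``centroid``
    (z, y, x in μm) and ``volume`` (μm³); nodes without a record get the
    origin and unit radius.  Spot ids are unique by construction.
    """
    records = records or {}
    nodes = sorted(forest.graph.nodes)
    stride = max((lab for _, lab in nodes), default=0) + 1
    root = etree.Element("TrackMate", version="7.11.1")
    model = etree.SubElement(root, "Model", spatialunits="µm", timeunits="min")
    allspots = etree.SubElement(model, "AllSpots", nspots=str(len(nodes)))
    frames = sorted({f for f, _ in nodes})
    for f in frames:
        sif = etree.SubElement(allspots, "SpotsInFrame", frame=str(f))
        for frame, label in (n for n in nodes if n[0] == f):
            rec = records.get((frame, label), {})
            z, y, x = rec.get("centroid", (0.0, 0.0, 0.0))
            vol = float(rec.get("volume", 4.0 * np.pi / 3.0))
            radius = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
            etree.SubElement(
                sif, "Spot",
                ID=str(_spot_id(frame, label, stride)),
                name=f"f{frame}_n{label}",
                FRAME=str(frame),
                POSITION_X=f"{x:.6f}", POSITION_Y=f"{y:.6f}",
                POSITION_Z=f"{z:.6f}",
                POSITION_T=f"{rec.get('time_minutes', 0.0):.3f}",
                RADIUS=f"{radius:.6f}", QUALITY="1.0",
            )
    alltracks = etree.SubElement(model, "AllTracks")
    und = forest.graph.to_undirected(as_view=True)
    comps = [sorted(c) for c in nx.connected_components(und)] if len(und) else []
    comps.sort()
    filtered = []
    for tid, comp in enumerate(comps):
        sub = forest.graph.subgraph(comp)
        if sub.number_of_edges() == 0:
            continue
        tr = etree.SubElement(alltracks, "Track", name=f"Track_{tid}",
                              TRACK_ID=str(tid),
                              NUMBER_SPOTS=str(len(comp)),
                              NUMBER_SPLITS=str(
                                  sum(1 for n in comp if sub.out_degree(n) == 2)))
        for u, v, d in sorted(sub.edges(data=True)):
            etree.SubElement(tr, "Edge",
                             SPOT_SOURCE_ID=str(_spot_id(*u, stride)),
                             SPOT_TARGET_ID=str(_spot_id(*v, stride)),
                             LINK_KIND=d.get("kind", "continuation"),
                             LINK_COST="0.0")
        filtered.append(tid)
    ft = etree.SubElement(model, "FilteredTracks")
    for tid in filtered:
        etree.SubElement(ft, "TrackID", TRACK_ID=str(tid))
    settings = etree.SubElement(root, "Settings")
    etree.SubElement(settings, "ImageData",
                     pixelwidth=f"{spacing[2]:.6f}", pixelheight=f"{spacing[1]:.6f}",
                     voxeldepth=f"{spacing[0]:.6f}", timeinterval="15.0")
    tree = etree.ElementTree(root)
    if path is not None:
        tree.write(str(path), pretty_print=True, xml_declaration=True,
                   encoding="UTF-8")
    return tree


def read_trackmate(source) -> tuple[LineageForest, dict]:
    """Parse a TrackMate-style file back into a forest + spot attribute dict.

    Validates spot-id uniqueness and that every edge endpoint exists.
    """
    if isinstance(source, (str, Path)):
        tree = etree.parse(str(source))
    else:
        tree = source
    root = tree.getroot()
    spots = {}
    by_id = {}
    for spot in root.iter("Spot"):
        sid = int(spot.get("ID"))
        if sid in by_id:
            raise DataFormatError(f"duplicate spot id {sid}")
        frame = int(spot.get("FRAME"))
        name = spot.get("name", "")
        label = int(name.split("_n")[1]) if "_n" in name else sid
        node = (frame, label)
        by_id[sid] = node
        spots[node] = dict(
            centroid=(float(spot.get("POSITION_Z")), float(spot.get("POSITION_Y")),
                      float(spot.get("POSITION_X"))),
            radius=float(spot.get("RADIUS")),
            time_minutes=float(spot.get("POSITION_T", 0.0)),
        )
    forest = LineageForest()
    for node in spots:
        forest.add_node(*node)
    for edge in root.iter("Edge"):
        s = int(edge.get("SPOT_SOURCE_ID"))
        t = int(edge.get("SPOT_TARGET_ID"))
        if s not in by_id or t not in by_id:
            raise DataFormatError(f"edge endpoint {s if s not in by_id else t} "
                                  "refers to a missing spot")
        forest.add_edge(by_id[s], by_id[t], kind=edge.get("LINK_KIND", "continuation"))
    forest.validate()
    return forest, spots
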