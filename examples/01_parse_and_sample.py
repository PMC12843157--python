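"""Parse mini-slicer G-code and sample the raw nozzle-centerline cloud.

Builds a small box scene, slices it, and shows what the parser recovers:
process metadata from the header comments, extrusion segments, and the
PC1 centerline point cloud sampled densely enough that voxelization at
0.10 mm cannot miss a cell.
"""

import gcodeqc as g

scene = g.compose_scene(g.make_box((10.0, 10.0, 2.0)))
code = g.mini_slice(scene)
tp = g.parse_gcode(code)

print(f"G-code lines:        {code.count(chr(10))}")
print(f"extrusion segments:  {tp.n_segments}")
print(f"layer height (mm):   {tp.meta.layer_height}  [{tp.meta.source['layer_height']}]")
print(f"line width (mm):     {tp.meta.line_width}  [{tp.meta.source['line_width']}]")
print(f"layers:              {tp.layer.max() + 1}")
print(f"total path (mm):     {tp.segment_lengths().sum():.1f}")

pc1 = g.extract_centerline_points(tp, spacing=0.05)
print(f"PC1 points:          {len(pc1)}")
# Each point lies exactly on its G-code segment; links follow print order
# and break at travel moves — that ordering is what later reconstructs
# layer contours.
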