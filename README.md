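# asternet

Structural analysis of self-assembled **actin aster networks** in
fluorescence micrographs.

When actin filaments are bundled by the depletion (entropic) forces of a
crowding agent such as methyl cellulose, they organise into large fields of
star-shaped units — *asters* — whose centres sit close to a triangular
lattice with a spacing of roughly 9–13 μm, connected by thick, often
multi-strand bundles. Quantifying these networks (how regular, how dense,
how homogeneous) requires locating every aster centre in a calibrated
micrograph and turning the point pattern into statistics. `asternet`
provides that pipeline, plus a ground-truthed synthetic image generator so
the whole chain can be validated by parameter recovery.

## What it computes

1. **Vertex detection.** Aster centres are junctions where many straight
   bundles converge. The image is cross-correlated with a bank of thin,
   zero-mean line kernels at angles *iπ/n* (default *n* = 15); the
   per-angle responses are summed, amplified by a second pass with
   elongated line kernels, blurred, thresholded, eroded and reduced to
   sub-pixel centroids. Detections closer than 3 μm are merged — such
   maxima are substructure of one junction, not distinct asters.
2. **Delaunay network statistics.** Detected centres are joined by a
   Delaunay triangulation. Edges shorter than 3 μm or longer than 20 μm
   are discarded (the long ones arise only at image edges or aster-free
   patches), then the pipeline reports the mean ± sd inter-vertex
   distance, the median number of connected neighbours with its IQR over
   interior vertices, and the vertex density scaled to 1 mm².
3. **Hexagon packing model.** A perfectly regular field with spacing *a*
   packs

   N(a) = (1000/a) · (1000 / ((√3/2)·a))   vertices per mm²,

   i.e. 2·10⁶/(√3 a²) with *a* in μm. The ratio of observed density to
   N(mean spacing) — the *hexagon correlation* — measures how close the
   network is to ideal triangular-lattice order (1.0 = perfect).
4. **Tile-bootstrap homogeneity.** The frame is split into 16 or 64 equal
   tiles, each tile's mean spacing is computed independently, and the tile
   means are bootstrap-resampled; a Gaussian kernel density estimate of the
   resampled means shows whether the field is spatially homogeneous.

## Worked example

Generate a 300 × 300 μm synthetic aster field (lattice constant 11 μm,
10% positional jitter) and analyse it:

```bash
asternet simulate --a-um 11 --jitter 0.1 --field-um 300 --seed 5 --out demo
asternet run --image demo/field.tif --pixel-um 0.36621 --seed 5 --out demo/report
```

which prints

```
wrote demo/field.tif (880 true vertices)
INFO asternet: detected 754 vertices after merging
INFO asternet: edges: 2158 retained, 0 short-rejected (<3 μm), 88 long-rejected (>20 μm)
Av Dist 11.3 um | Neighb 6 | Vert. Dens 8,382 /mm2 | Corr. Hex 0.920
```

Reading: the detected mean inter-vertex distance (11.3 μm) recovers the
11 μm lattice constant; every interior vertex has the hexagonal median of
6 Delaunay neighbours; and the observed density is within 8% of the
hexagon-model prediction at this field size (the deficit is the border
band where asters cannot be detected — it shrinks as the imaged area
grows; on the default 750 μm field the deviation is ≈ 4%). The same steps
are available as a library:

```python
import asternet as an

spec = an.AsterFieldSpec(seed=5)           # 750×750 μm, a = 11 μm
truth, frame = an.simulate_field(spec)
report = an.run_full_analysis(frame, an.PipelineConfig(pixel_size_um=spec.pixel_size_um))
print(report.summary.mean_edge_length_um, report.summary.median_degree)
```

`asternet detect` and `asternet analyze` expose the two pipeline halves
separately (vertex CSV in between); `run` is exactly their composition.

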