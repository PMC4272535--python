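"""Cluster chemotactically aggregating cells and score cluster validity.

Simulates 100 biased random walkers on a 100x100 lattice with a Gaussian
attractant, detects single-cell entities at three timepoints, groups them
with the order-independent DBSCAN, and prints cluster measures plus the
Silhouette index.
"""

from stmc import (
    ChemotaxisGeneratorConfig,
    ClusterDetectionConfig,
    RegionDetectionConfig,
    SpaceGeometry,
    cluster_measures,
    detect_clusters,
    detect_regions,
    generate_chemotaxis_trace,
    grid_to_grayscale,
    silhouette_index,
)

cfg = ChemotaxisGeneratorConfig(seed=0, attraction_strength=1.0)
trace = generate_chemotaxis_trace(cfg)
geom = SpaceGeometry(rows=100, cols=100)
point_detector = RegionDetectionConfig(point_mode=True, threshold_value=1)
clustering = ClusterDetectionConfig(epsilon_distance=3.0, epsilon_size=4)

for t in (10, 60, 200):
    cells, _ = trace[t]
    points = detect_regions(grid_to_grayscale(cells, "auto"), point_detector)
    clusters = detect_clusters(points, clustering)
    silhouette = silhouette_index(clusters)
    print(f"t={t:3d}: {len(points):3d} occupied positions, "
          f"{len(clusters)} clusters"
          + (f", Silhouette={silhouette:.3f}" if silhouette is not None else ""))
    for i, cluster in enumerate(clusters):
        m = cluster_measures(cluster, cells, geom)
        print(f"   cluster {i}: members={len(cluster.members):3d}  "
              f"distanceFromOrigin={m.distanceFromOrigin:5.1f}  "
              f"circular={m.circularMeasure:.2f}  shape={m.shape}")
print("Cells coalesce toward the attractant peak at the grid centre: cluster")
print("count drops, distance from the origin shrinks, shapes become circular.")
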