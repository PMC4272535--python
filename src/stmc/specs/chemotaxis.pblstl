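# Chemotaxis case study: aggregation of 100 cells toward a static 2-D
# Gaussian attractant centred on a 100x100 lattice (clusters of single-cell
# detections, timepoints 0..200).  Statement numbering continues the
# phase-variation list (9..14).  The attractant centre coincides with the
# origin of the discretised space at (49.5, 49.5), so proximity to the
# gradient centre is expressed through distanceFromOrigin.

# 9. Cells aggregate near the point of highest attractant concentration:
#    eventually at least one cluster forms within distance 50 of the centre.
P >= 0.9 [ F [0, 200] (count(filter(clusters, distanceFromOrigin < 50)) > 0) ]

# 10. The average clusteredness degree of the clusters increases at least
#     five times during the simulation interval.
P > 0.8 [ F [0, 39] ((d(mean(clusters, clusteredness)) > 0) ^
          F [1, 39] ((d(mean(clusters, clusteredness)) > 0) ^
          F [1, 39] ((d(mean(clusters, clusteredness)) > 0) ^
          F [1, 39] ((d(mean(clusters, clusteredness)) > 0) ^
          F [1, 39] (d(mean(clusters, clusteredness)) > 0))))) ]

# 11. The Silhouette cluster-validity index (recorded per timepoint as the
#     numeric state variable avgClusterednessClusters) rarely loses cluster
#     structure (values near 0 mean overlapping clusters) in the early
#     interval.  The threshold is calibrated to the cluster geometry of the
#     packaged synthetic generator.
P < 0.05 [ F [0, 50] ({avgClusterednessClusters} < 0.1) ]

# 12. The number of clusters decreases and then remains below 5: small
#     initial clusters merge near the attractant peak.
P > 0.75 [ F [0, 150] (G [0, 50] (count(clusters) < 5)) ]

# 13. At least one aggregated cluster eventually has a circular-like shape
#     (areas of equal attractant concentration are rings).
P >= 0.6 [ F [0, 200] (max(clusters, circularMeasure) > 0.6) ]

# 14. The average cluster density almost never stays monotone: oscillations
#     are expected because cells pile up.
P < 0.1 [ ~ ( F [0, 150] ((d(mean(clusters, density)) > 0) ^ F [1, 45] (d(mean(clusters, density)) < 0))
            V F [0, 150] ((d(mean(clusters, density)) < 0) ^ F [1, 45] (d(mean(clusters, density)) > 0)) ) ]
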