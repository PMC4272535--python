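# Phase-variation case study: sector-like patterns in a growing bacterial
# colony (regions detected on the mutant-fraction grid of a 101x101 space,
# timepoints 0..39).  Statement numbering follows the natural-language
# specification list.

# 1. The number of sector-like patterns never decreases during growth.
P >= 0.95 [ G [0, 38] (d(count(regions)) >= 0) ]

# 2. Sectors containing holes are rare: the probability that the minimum
#    clusteredness degree of the sectors drops below 0.9 is small.
P < 0.05 [ F [0, 39] (min(regions, clusteredness) < 0.9) ]

# 3. Detected sectors are dominated by switched cells: once sectors exist,
#    their average relative density exceeds 0.5.
P > 0.95 [ G [10, 39] ((count(regions) = 0) V (mean(regions, density) > 0.5)) ]

# 4. The average sector area oscillates at least once: its rate of change
#    is positive and then eventually negative, or vice versa.
P > 0.5 [ F [0, 30] ((d(mean(regions, area)) > 0) ^ F [1, 8] (d(mean(regions, area)) < 0))
        V F [0, 30] ((d(mean(regions, area)) < 0) ^ F [1, 8] (d(mean(regions, area)) > 0)) ]

# 5. The average sector perimeter oscillates at least five times
#    (alternating signs of its rate of change; deeply nested windows).
P > 0.6 [ F [0, 5] ((d(mean(regions, perimeter)) > 0) ^
          F [1, 2] ((d(mean(regions, perimeter)) < 0) ^
          F [1, 2] ((d(mean(regions, perimeter)) > 0) ^
          F [1, 2] ((d(mean(regions, perimeter)) < 0) ^
          F [1, 2] ((d(mean(regions, perimeter)) > 0) ^
          F [1, 2] ((d(mean(regions, perimeter)) < 0) ^
          F [1, 2] ((d(mean(regions, perimeter)) > 0) ^
          F [1, 2] ((d(mean(regions, perimeter)) < 0) ^
          F [1, 2] ((d(mean(regions, perimeter)) > 0) ^
          F [1, 2] (d(mean(regions, perimeter)) < 0)))))))))) ]

# 6. Sectors subtending more than 120 degrees at the origin are unlikely.
P < 0.1 [ F [0, 39] (max(regions, angle) > 120) ]

# 7. Sectors develop from the origin outwards, so every sector stays close
#    to the origin (distance below 20 lattice units on the 101x101 grid).
P >= 0.95 [ G [10, 39] ((count(regions) = 0) V (min(regions, distanceFromOrigin) < 20)) ]

# 8. Most sectors develop and maintain a triangular-like shape.
P > 0.8 [ G [10, 39] ((count(regions) = 0) V
                      (mean(regions, triangularMeasure) >= mean(regions, rectangularMeasure))) ]
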