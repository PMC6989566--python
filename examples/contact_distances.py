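"""Minimum contact distances in a (toy) trajectory, with a conformer split.

Generates a bimodal synthetic trajectory — the photosensitizer hopping
between a wedged-in and a rotated-out conformation — and summarizes the
per-frame minimum distance between the two atom sets.
"""

from chirospec import AtomSelection, conformer_split, min_distance_series
from chirospec.synthetic import generate_trajectory

traj, truth = generate_trajectory(n_frames=1000, n_atoms_a=10, n_atoms_b=10,
                                  target_mean=6.5, target_sd=0.5,
                                  modes=2, mode_separation=5.0, seed=7)
series = min_distance_series(traj,
                             AtomSelection("chromophore", truth["selection_a"]),
                             AtomSelection("heme", truth["selection_b"]))
print(f"frames analyzed      : {len(series)}")
print(f"min distance         : {series.mean:.2f} ± {series.sd:.2f} Å (mean ± sd)")

split = conformer_split(series, threshold=6.5)
print(f"proximal conformer   : {split.proximal.mean:.2f} Å, "
      f"occupancy {split.proximal.occupancy:.2f}")
print(f"distal conformer     : {split.distal.mean:.2f} Å, "
      f"occupancy {split.distal.occupancy:.2f}")
print()
print("The per-frame minimum over all cross pairs of non-hydrogen atoms is a "
      "proxy for donor–acceptor electronic coupling; a narrow distribution "
      "means a sterically locked chromophore, and the threshold split "
      "quantifies how a flexible site partitions between two conformations.")
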