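# vbstruct

Generation, ranking and selection of valence-bond spin-coupling (HLSP)
structure sets.

Given an active space (n orbitals, n_electrons electrons, total spin S with
per-orbital atom and symmetry metadata), the package:

- **enumerates** every structure — lone pairs, vacant orbitals,
  singlet-coupled pairs and 2S radicals — grouped into lone-pair/vacant
  *subspaces* (`vbstruct.vb_space`);
- **expands** structures over spin-orbital determinants, builds Gramians of
  the unit-normalized structure vectors and decides linear independence by
  an eigenvalue threshold (default `1e-11`); includes the branching-diagram
  count of independent structures and a Chirgwin–Coulson weight utility for
  externally supplied coefficients/overlaps (`vbstruct.spin_algebra`);
- implements the full **Rumer engine**: non-crossing circle diagrams with
  dummy centers for unpaired electrons, Rumer-set generation for any
  orbital ordering, distinct-bond counting, and brute-force enumeration of
  all distinct Rumer sets over the N! orderings with deduplication
  (`vbstruct.rumer`);
- **ranks** structures by five chemical-quality criteria — user-defined
  bonds, user-defined radicals, intra-atomic bonds, bond length (relative
  stretch vs. summed covalent radii) and orbital symmetry — merged
  lexicographically by a user-chosen priority order (`vbstruct.ranking`);
- **selects** a complete linearly independent set per subspace by greedily
  adding the best-ranked structures whose inclusion keeps the Gramian
  invertible, with optional user-pinned structures that the method
  complements to a full set (`vbstruct.selection`);
- provides XYZ/YAML/matrix readers, the occupancy structure notation
  (`[1 1 2 2] 3 3 4-6 5-7`), four built-in example systems (`c5h5`,
  `h_oh_ts`, `hnc_ts`, `c2`) and the CLI (`vbstruct.io_cli`).

## CLI

```sh
vbstruct count --system c5h5 --covalent-only
vbstruct enumerate --system hnc_ts --covalent-only
vbstruct rumer --system c2 --ordering 1,5,2,6,3,7,4,8
vbstruct rank --system c5h5 --priorities intra_atomic,bond_length
vbstruct select --system h_oh_ts --pin "3 4 1-2" --pin "1 4 2-3"
vbstruct weights --coefficients c.txt --overlaps s.txt
```

Custom systems are YAML configs (see `vbstruct.io_cli.load_config`):

```yaml
n_orbitals: 4
n_electrons: 4
spin: 2            # stored as 2S (integer)
orbitals:
  - {index: 1, atom: H1, symmetry: sigma}
  - {index: 2, atom: H2, symmetry: sigma}
  - {index: 3, atom: O1, symmetry: sigma}
  - {index: 4, atom: O1, symmetry: pi}
criteria:
  priorities: [user_bonds, intra_atomic]
  user_bonds: ["1-2", "2-3"]
```

Geometries are standard XYZ files (Å); covalent radii default to the
crystallographic (Cordero) table and can be overridden via the config's
`radii` map.

## Notes

- Structure vectors are unit-normalized before the Gramian, so the
  eigenvalue threshold is scale-free.
- The bond-length criterion depends on the geometry; the CLI warns when it
  is the top-priority criterion.
- Computing structure weights of an optimized wavefunction requires an
  electronic-structure engine and is out of scope; the weight formula is
  exposed as a utility for externally supplied coefficients and overlaps.
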