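"""Generate the standard six-family synthetic fixture and write it to disk.

Five families carry planted cofactor key residues (two heme variants,
FAD, FMN, PYP) at structural-element columns of a 110-residue scaffold;
a sixth family is motif-free.  10% of each family's members violate the
motif, mimicking real clusters where key residues are conserved in only
part of the family.
"""

import tempfile

from pas_atlas.synthetic import (GenomeSpec, generate_families,
                                 generate_genomes, standard_element_maps,
                                 standard_family_specs, write_fixture)

specs = standard_family_specs()
sequences, truth = generate_families(specs, seed=1)
genomes = generate_genomes(GenomeSpec(n_genomes=200, rng_seed=1))

out = tempfile.mkdtemp(prefix="pas_fixture_")
paths = write_fixture(sequences, truth, genomes, out,
                      element_maps=standard_element_maps(specs))

print(f"{len(sequences)} sequences in {len(specs)} families, "
      f"{len(genomes)} genomes")
for label, path in paths.items():
    print(f"  {label}: {path}")
example = sequences[0]
print(f"first record: {example.id} ({len(example)} aa), "
      f"family={truth.sequence_to_family[example.id]}, "
      f"cofactor={truth.family_to_cofactor[example.family_hint]}")
print(f"planted motif columns for heme_Fa: {truth.motif_columns['heme_Fa']} "
      "(column -> required residue on the ancestor scaffold)")
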