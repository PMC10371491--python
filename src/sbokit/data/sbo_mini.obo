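format-version: 1.2
data-version: sbokit-mini/2025-09
ontology: sbo-mini
remark: Hand-curated miniature subset of the Systems Biology Ontology (synthetic fixture). It contains only the terms referenced by sbokit's default configuration and mapping seed, plus their is-a ancestor chains. It is NOT a full SBO release.

[Term]
id: SBO:0000000
name: systems biology representation

[Term]
id: SBO:0000003
name: participant role
is_a: SBO:0000000 ! systems biology representation

[Term]
id: SBO:0000013
name: catalyst
is_a: SBO:0000003 ! participant role

[Term]
id: SBO:0000460
name: enzymatic catalyst
is_a: SBO:0000013 ! catalyst

[Term]
id: SBO:0000231
name: occurring entity representation
is_a: SBO:0000000 ! systems biology representation

[Term]
id: SBO:0000375
name: process
is_a: SBO:0000231 ! occurring entity representation

[Term]
id: SBO:0000176
name: biochemical reaction
is_a: SBO:0000375 ! process

[Term]
id: SBO:0000200
name: redox reaction
is_a: SBO:0000176 ! biochemical reaction

[Term]
id: SBO:0000201
name: oxidation
is_a: SBO:0000200 ! redox reaction

[Term]
id: SBO:0000202
name: reduction
is_a: SBO:0000200 ! redox reaction

[Term]
id: SBO:0000178
name: cleavage
is_a: SBO:0000176 ! biochemical reaction

[Term]
id: SBO:0000212
name: isomerisation
is_a: SBO:0000176 ! biochemical reaction

[Term]
id: SBO:0000376
name: hydrolysis
is_a: SBO:0000176 ! biochemical reaction

[Term]
id: SBO:0000695
name: formation of a covalent bond
is_a: SBO:0000176 ! biochemical reaction

[Term]
id: SBO:0000402
name: transfer of a chemical group
is_a: SBO:0000176 ! biochemical reaction

[Term]
id: SBO:0000403
name: transamination
is_a: SBO:0000402 ! transfer of a chemical group

[Term]
id: SBO:0000213
name: glycosylation
is_a: SBO:0000402 ! transfer of a chemical group

[Term]
id: SBO:0000214
name: phosphorylation
is_a: SBO:0000402 ! transfer of a chemical group

[Term]
id: SBO:0000217
name: methylation
is_a: SBO:0000402 ! transfer of a chemical group

[Term]
id: SBO:0000219
name: sulfation
is_a: SBO:0000402 ! transfer of a chemical group

[Term]
id: SBO:0000210
name: addition of a chemical group
is_a: SBO:0000402 ! transfer of a chemical group

[Term]
id: SBO:0000215
name: acetylation
is_a: SBO:0000210 ! addition of a chemical group

[Term]
id: SBO:0000216
name: ubiquitination
is_a: SBO:0000210 ! addition of a chemical group

[Term]
id: SBO:0000218
name: myristoylation
is_a: SBO:0000210 ! addition of a chemical group

[Term]
id: SBO:0000224
name: palmitoylation
is_a: SBO:0000210 ! addition of a chemical group

[Term]
id: SBO:0000233
name: hydroxylation
is_a: SBO:0000210 ! addition of a chemical group

[Term]
id: SBO:0000220
name: prenylation
is_a: SBO:0000210 ! addition of a chemical group

[Term]
id: SBO:0000222
name: geranylation
is_a: SBO:0000220 ! prenylation

[Term]
id: SBO:0000223
name: farnesylation
is_a: SBO:0000220 ! prenylation

[Term]
id: SBO:0000185
name: translocation reaction
is_a: SBO:0000375 ! process

[Term]
id: SBO:0000655
name: transport reaction
is_a: SBO:0000185 ! translocation reaction

[Term]
id: SBO:0000657
name: active transport
is_a: SBO:0000655 ! transport reaction

[Term]
id: SBO:0000659
name: symporter-mediated transport
is_a: SBO:0000657 ! active transport

[Term]
id: SBO:0000660
name: antiporter-mediated transport
is_a: SBO:0000657 ! active transport

[Term]
id: SBO:0000658
name: passive transport
is_a: SBO:0000655 ! transport reaction

[Term]
id: SBO:0000631
name: pseudoreaction
is_a: SBO:0000375 ! process

[Term]
id: SBO:0000627
name: exchange reaction
is_a: SBO:0000631 ! pseudoreaction

[Term]
id: SBO:0000628
name: demand reaction
is_a: SBO:0000631 ! pseudoreaction

[Term]
id: SBO:0000632
name: sink reaction
is_a: SBO:0000631 ! pseudoreaction

[Term]
id: SBO:0000629
name: biomass production
is_a: SBO:0000631 ! pseudoreaction

[Term]
id: SBO:0000630
name: ATP maintenance
is_a: SBO:0000631 ! pseudoreaction

[Term]
id: SBO:0000236
name: physical entity representation
is_a: SBO:0000000 ! systems biology representation

[Term]
id: SBO:0000240
name: material entity
is_a: SBO:0000236 ! physical entity representation

[Term]
id: SBO:0000247
name: simple chemical
is_a: SBO:0000240 ! material entity

[Term]
id: SBO:0000245
name: macromolecule
is_a: SBO:0000240 ! material entity

[Term]
id: SBO:0000243
name: gene
is_a: SBO:0000240 ! material entity
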