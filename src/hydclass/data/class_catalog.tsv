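code	type	name	predicted_function	provenance
1a	NiFe	Periplasmic	Electron input for sulfate, metal, and organohalide respiration. [NiFeSe] variants.	prior work
1b	NiFe	Prototypical	Electron input for sulfate, fumarate, metal, and nitrate respiration.	prior work
1c	NiFe	Hyb-type	Electron input for fumarate, nitrate, and sulfate respiration. Physiologically reversible.	prior work
1d	NiFe	Oxygen-tolerant	Electron input for aerobic respiration and oxygen-tolerant anaerobic respiration.	prior work
1e	NiFe	Isp-type	Electron input primarily for sulfur respiration. Physiologically reversible.	prior work
1f	NiFe	Oxygen-protecting	Unresolved role. May liberate electrons to reduce reactive oxygen species.	prior work
1g	NiFe	Crenarchaeota-type	Electron input primarily for sulfur respiration.	prior work
1h	NiFe	Actinobacteria-type	Electron input for aerobic respiration. Scavenges electrons from atmospheric H2.	prior work
1i	NiFe	Coriobacteria-type (putative)	Undetermined role. May liberate electrons for anaerobic respiration.	This work
1j	NiFe	Archaeoglobi-type	Electron input for sulfate respiration.	This work
1k	NiFe	Methanophenazine-reducing	Electron input for methanogenic heterodisulfide respiration.	This work
2a	NiFe	Cyanobacteria-type	Electron input for aerobic respiration. Recycles H2 produced by other cellular processes.	prior work
2b	NiFe	Histidine kinase-linked	H2 sensing. Activates two-component system controlling hydrogenase expression.	prior work
2c	NiFe	Diguanylate cyclase-linked (putative)	Undetermined role. May sense H2 and regulate processes through cyclic di-GMP production.	prior work
2d	NiFe	Aquificae-type	Unresolved role. May generate reductant for carbon fixation or have a regulatory role.	prior work
2e	NiFe	Metallosphaera-type (putative)	Undetermined role. May liberate electrons primarily for aerobic respiration.	This work
3a	NiFe	F420-coupled	Couples oxidation of H2 to reduction of F420 during methanogenesis. Physiologically reversible. [NiFeSe] variants.	prior work
3b	NiFe	NADP-coupled	Couples oxidation of NADPH to evolution of H2. Physiologically reversible. May have sulfhydrogenase activity.	prior work
3c	NiFe	Heterodisulfide reductase-linked	Bifurcates electrons from H2 to heterodisulfide and Fdox in methanogens. [NiFeSe] variants.	prior work
3d	NiFe	NAD-coupled	Interconverts electrons between H2 and NAD depending on cellular redox state.	prior work
4a	NiFe	Formate hydrogenlyase	Couples formate oxidation to fermentative H2 evolution. May be H+-translocating.	prior work
4b	NiFe	Formate-respiring	Respires formate or carbon monoxide using H+ as electron acceptor. Na+-translocating via Mrp.	This work
4c	NiFe	Carbon monoxide-respiring	Respires carbon monoxide using H+ as electron acceptor. H+-translocating.	prior work
4d	NiFe	Ferredoxin-coupled, Mrp-linked	Couples Fdred oxidation to H+ reduction. Na+-translocating via Mrp complex.	This work
4e	NiFe	Ferredoxin-coupled, Ech-type	Couples Fdred oxidation to H+ reduction. Physiologically reversible via H+/Na+ translocation.	prior work
4f	NiFe	Formate-coupled (putative)	Undetermined role. May couple formate oxidation to H2 evolution and H+ translocation.	prior work
4g	NiFe	Ferredoxin-coupled (putative)	Undetermined role. May couple Fdred oxidation to proton reduction and H+/Na+ translocation.	This work
4h	NiFe	Ferredoxin-coupled, Eha-type	Couples Fdred oxidation to H+ reduction in anaplerotic processes. H+/Na+-translocating.	This work
4i	NiFe	Ferredoxin-coupled, Ehb-type	Couples Fdred oxidation to H+ reduction in anabolic processes. H+/Na+-translocating.	This work
A1	FeFe	Prototypical	Couples ferredoxin oxidation to fermentative or photobiological H2 evolution.	prior work
A2	FeFe	Glutamate synthase-linked (putative)	Undetermined role. May couple H2 oxidation to NAD reduction, generating reductant for glutamate synthase.	prior work
A3	FeFe	Bifurcating	Reversibly bifurcates electrons from H2 to NAD and Fdox in anaerobic bacteria.	prior work
A4	FeFe	Formate dehydrogenase-linked	Couples formate oxidation to H2 evolution. Some bifurcate electrons from H2 to ferredoxin and NADP.	prior work
B	FeFe	Colonic-type (putative)	Undetermined role. May couple Fdred oxidation to fermentative H2 evolution.	prior work
C1	FeFe	Histidine kinase-linked (putative)	Undetermined role. May sense H2 and regulate processes via histidine kinases.	This work
C2	FeFe	Chemotactic (putative)	Undetermined role. May sense H2 and regulate processes via methyl-accepting chemotaxis proteins.	This work
C3	FeFe	Phosphatase-linked (putative)	Undetermined role. May sense H2 and regulate processes via serine/threonine phosphatases.	This work
Fe	Fe	Methenyl-H4MPT dehydrogenase	Reversibly couples H2 oxidation to 5,10-methenyltetrahydromethanopterin reduction.	prior work
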