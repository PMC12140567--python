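region	lobe
lh-bankssts	temporal
lh-caudalanteriorcingulate	cingulate
lh-caudalmiddlefrontal	frontal
lh-cuneus	occipital
lh-entorhinal	temporal
lh-fusiform	temporal
lh-inferiorparietal	parietal
lh-inferiortemporal	temporal
lh-isthmuscingulate	cingulate
lh-lateraloccipital	occipital
lh-lateralorbitofrontal	frontal
lh-lingual	occipital
lh-medialorbitofrontal	frontal
lh-middletemporal	temporal
lh-parahippocampal	temporal
lh-paracentral	frontal
lh-parsopercularis	frontal
lh-parsorbitalis	frontal
lh-parstriangularis	frontal
lh-pericalcarine	occipital
lh-postcentral	parietal
lh-posteriorcingulate	cingulate
lh-precentral	frontal
lh-precuneus	parietal
lh-rostralanteriorcingulate	cingulate
lh-rostralmiddlefrontal	frontal
lh-superiorfrontal	frontal
lh-superiorparietal	parietal
lh-superiortemporal	temporal
lh-supramarginal	parietal
lh-frontalpole	frontal
lh-temporalpole	temporal
lh-transversetemporal	temporal
lh-insula	insula
rh-bankssts	temporal
rh-caudalanteriorcingulate	cingulate
rh-caudalmiddlefrontal	frontal
rh-cuneus	occipital
rh-entorhinal	temporal
rh-fusiform	temporal
rh-inferiorparietal	parietal
rh-inferiortemporal	temporal
rh-isthmuscingulate	cingulate
rh-lateraloccipital	occipital
rh-lateralorbitofrontal	frontal
rh-lingual	occipital
rh-medialorbitofrontal	frontal
rh-middletemporal	temporal
rh-parahippocampal	temporal
rh-paracentral	frontal
rh-parsopercularis	frontal
rh-parsorbitalis	frontal
rh-parstriangularis	frontal
rh-pericalcarine	occipital
rh-postcentral	parietal
rh-posteriorcingulate	cingulate
rh-precentral	frontal
rh-precuneus	parietal
rh-rostralanteriorcingulate	cingulate
rh-rostralmiddlefrontal	frontal
rh-superiorfrontal	frontal
rh-superiorparietal	parietal
rh-superiortemporal	temporal
rh-supramarginal	parietal
rh-frontalpole	frontal
rh-temporalpole	temporal
rh-transversetemporal	temporal
rh-insula	insula
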