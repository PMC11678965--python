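task,group,feature_set,accuracy
TUG,mild,trial1,75.3
TUG,mild,trial2,73.6
TUG,mild,both,74.5
TUG,mild,duration_only,59.3
cogTUG,mild,trial1,81.7
cogTUG,mild,trial2,76.6
cogTUG,mild,both,81.7
cogTUG,mild,duration_only,57.6
walk16ft,mild,trial1,66.0
walk16ft,mild,trial2,66.8
walk16ft,mild,both,69.8
walk16ft,mild,duration_only,62.3
TUG,moderate,trial1,80.9
TUG,moderate,trial2,80.9
TUG,moderate,both,80.0
TUG,moderate,duration_only,80.0
cogTUG,moderate,trial1,82.7
cogTUG,moderate,trial2,79.1
cogTUG,moderate,both,82.7
cogTUG,moderate,duration_only,80.9
walk16ft,moderate,trial1,74.5
walk16ft,moderate,trial2,70.9
walk16ft,moderate,both,73.6
walk16ft,moderate,duration_only,71.5
TUG,severe,trial1,91.0
TUG,severe,trial2,94.0
TUG,severe,both,94.0
TUG,severe,duration_only,85.2
cogTUG,severe,trial1,95.5
cogTUG,severe,trial2,89.6
cogTUG,severe,both,89.6
cogTUG,severe,duration_only,88.6
walk16ft,severe,trial1,86.6
walk16ft,severe,trial2,86.6
walk16ft,severe,both,91.0
walk16ft,severe,duration_only,86.2
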