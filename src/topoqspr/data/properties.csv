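drug,boiling_point,melting_point,enthalpy,flash_point,molar_refractivity,polarizability,surface_tension,molar_volume
Alprazolam,509,228.25,77.9,261.6,88.2,35,52.2,225.6
Amitriptyline,398.2,196,64.9,174,91.5,36.3,47,257.8
Amoxapine,469.9,175.5,73.2,238,86.8,34.4,52.1,228.2
Buspirone,613.9,202,91.1,325.1,106.8,42.4,62.4,310.7
Clomipramine,434.2,189.5,69,216.4,93.8,37.2,41.7,281.2
Desipramine,407.4,25,65.9,160.5,84.2,33.4,40,254.3
Desvenlafaxine,403.8,208,69.1,193.2,77.8,30.9,47.9,236.1
Diazepam,497.4,125,76.5,254.6,80.9,32.1,46.1,225.9
Fluoxetine,395.1,180.5,64.5,192.8,79.9,31.7,33,266.7
Imipramine,403.1,174.5,65.4,179.7,88.9,35.3,40.1,269.2
Lorazepam,543.6,167,86.5,282.6,81,32.1,56,211.2
Nortriptyline,403.4,214,65.5,194.9,86.8,34.4,47.3,242.9
Oxazepam,516.6,205.5,83,266.2,76.4,30.3,54.6,201.9
Protriptyline,407.7,170,66,198.3,84.8,33.6,41.2,256.5
Trimipramine,411.8,45,66.4,183.3,93.5,37.1,39.1,286.1
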