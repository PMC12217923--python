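drug,wiener,hyper_wiener,harary,detour,detour_harary
Alprazolam,926,2770,81.4698,2845,24.1903
Amitriptyline,882,2780,70.1254,2581,26.2091
Amoxapine,936,2813,80.7849,3005,22.4103
Buspirone,2514,13028,102.7360,3764,57.3298
Clomipramine,995,3194,78.0429,2861,28.6732
Desipramine,759,2282,68.0484,2328,22.5787
Desvenlafaxine,672,1979,61.8337,1056,38.8190
Diazepam,726,2077,69.4905,1901,24.9069
Fluoxetine,1148,4312,72.9427,1604,49.6266
Imipramine,882,2780,70.1256,2581,26.2091
Lorazepam,819,2365,74.9607,2148,27.8257
Nortriptyline,759,2282,68.0484,2328,22.5787
Oxazepam,727,2076,69.3488,1909,24.8700
Protriptyline,759,2282,68.0484,2328,22.5787
Trimipramine,979,3081,78.4616,2808,30.3429
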