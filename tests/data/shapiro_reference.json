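{
 "seed": 20260,
 "W": [
  0.9952075326656,
  0.8479656231382,
  0.9593742223377,
  0.5701010820503,
  0.9615181690895,
  0.9761398358898,
  0.8275507488481,
  0.9517294893471,
  0.6923932281254,
  0.8894002690066,
  0.9899895928208,
  0.8100219835808,
  0.9662528594664,
  0.4816814395597,
  0.4927472134787,
  0.9930940352111,
  0.8084391652148,
  0.9469145242011,
  0.7322005299776,
  0.8896972480883,
  0.9881079123573,
  0.8224896773692,
  0.9473824463565,
  0.7979313861823,
  0.8311188615501,
  0.9921603500801,
  0.7772224137626,
  0.8839385693162,
  0.7537207690335,
  0.9384040594185,
  0.9842247705705,
  0.8493993896076,
  0.9474658916005,
  0.615732168384,
  0.9644713745309,
  0.96475937455,
  0.8221863225725,
  0.9506789438181,
  0.6026551732669,
  0.8691204680423,
  0.9935434682222,
  0.8091894898635,
  0.9510921763571,
  0.746871500358,
  0.9225287028191,
  0.976752229037,
  0.7736659129843,
  0.9567869695706,
  0.6191394405819,
  0.9707657909077
 ],
 "p": [
  0.9683790269258,
  7.99386666348e-08,
  3.298194998708e-06,
  1.743848293844e-15,
  0.3999697075162,
  0.1808407775235,
  1.139438067584e-14,
  0.000722685001039,
  6.059347968761e-09,
  5.455200705802e-09,
  0.05329992560503,
  2.959907739399e-10,
  0.04767036366767,
  1.370734230059e-25,
  4.613183266929e-25,
  0.4887748995619,
  4.609371606297e-15,
  1.43920440753e-08,
  7.407548124996e-16,
  2.125691688946e-09,
  0.0258624788655,
  1.80687552332e-14,
  8.482453691423e-08,
  1.482028905743e-05,
  1.282724458686e-12,
  0.1243177099417,
  1.901676177634e-15,
  0.0007887638963581,
  2.247710882428e-20,
  2.516548240201e-09,
  0.166692324717,
  3.130931919613e-12,
  0.0004580253387485,
  4.47236889424e-23,
  0.004243952842602,
  0.387526485796,
  5.46239483195e-11,
  5.866539014192e-06,
  2.743280495976e-05,
  3.652121080063e-15,
  0.8318947915344,
  6.741807657323e-14,
  3.781000107764e-07,
  3.737077888288e-15,
  5.737887609002e-07,
  0.2104245850785,
  4.240121227687e-18,
  0.001455262856657,
  1.89582329337e-16,
  0.2956932463026
 ]
}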