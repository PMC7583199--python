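# Synthetic oxy/deoxy-hemoglobin molar extinction spectrum, 400-600 nm, 2 nm step.
# SYNTHETIC reconstruction: monotone (PCHIP) interpolation through approximate
# anchor values transcribed from the standard compiled whole-blood tabulations
# of hemoglobin extinction. Qualitative spectral shape is preserved (Soret and
# Q bands, isosbestic crossings near 421/500/547/570/583 nm, deoxy > oxy at
# both 445 and 473 nm); values are NOT metrologically accurate and must not be
# used for quantitative spectroscopy outside this package's simulations.
# Units: molar extinction coefficient, cm^-1 M^-1 (decadic), per hemoglobin
# tetramer (molar mass 64,500 g/mol).
# columns: wavelength_nm,eps_oxy,eps_deoxy
400,266000.0,224000.0
402,311774.3,239062.8
404,354445.8,255167.4
406,393894.4,272188.4
408,430000.0,290000.0
410,468619.6,308842.6
412,504309.8,328908.5
414,520000.0,350000.0
416,510951.8,372460.3
418,488570.3,396117.3
420,460000.0,420000.0
422,416640.2,444405.6
424,358433.6,468671.9
426,301054.4,492181.8
428,239255.8,517636.4
430,190000.0,530000.0
432,157229.1,523965.7
434,132498.9,509154.3
436,117635.3,486198.8
438,107934.8,440723.0
440,100000.0,390000.0
442,92921.8,344628.0
444,86493.4,296669.3
446,78989.2,236486.2
448,70177.2,156164.3
450,62816.0,103292.0
452,57863.5,86636.2
454,53851.4,76163.9
456,50201.5,68176.6
458,46881.6,61828.6
460,44000.0,57000.0
462,41442.0,53104.5
464,39056.0,49698.2
466,36870.0,46739.6
468,34911.7,44187.3
470,33209.0,42000.0
472,31831.5,40249.3
474,30629.4,38766.5
476,29306.6,37192.4
478,27851.4,35565.6
480,26629.0,34000.0
482,25711.1,32518.4
484,24901.6,31080.7
486,24188.2,29683.7
488,23558.5,28324.5
490,23000.0,27000.0
492,22447.7,25615.9
494,21892.7,24171.9
496,21407.0,22806.1
498,21062.8,21656.8
500,20932.0,20862.0
502,21199.9,20302.6
504,21898.5,19795.1
506,22869.9,19381.1
508,23956.3,19102.2
510,25000.0,19000.0
512,26019.5,19202.3
514,27134.9,19726.9
516,28340.5,20450.3
518,29630.7,21249.1
520,31000.0,22000.0
522,32448.4,22684.2
524,33996.8,23389.7
526,35671.1,24153.1
528,37496.9,25011.0
530,39500.0,26000.0
532,42272.7,27178.7
534,45847.3,28576.0
536,49409.1,30184.0
538,52143.5,31994.7
540,53236.0,34000.0
542,52784.3,36360.6
544,51679.7,39294.2
546,49942.1,43322.3
548,46479.1,49387.6
550,43016.0,53412.0
552,40397.4,54661.7
554,38055.6,55397.2
556,35894.3,55397.4
558,33670.1,54730.2
560,32613.0,53788.0
562,33087.0,52526.3
564,34263.4,50866.8
566,36130.5,49081.9
568,39965.3,47037.6
570,44496.0,45072.0
572,49789.7,43345.5
574,55162.2,41746.1
576,58390.9,40158.3
578,60000.0,39000.0
580,56507.6,39198.3
582,48352.9,39606.4
584,39019.8,39944.6
586,31230.6,39535.5
588,23405.3,36649.9
590,17000.0,33000.0
592,12433.5,29166.3
594,8847.8,24939.3
596,6349.4,21211.1
598,4390.1,17812.3
600,3200.0,14677.0
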