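wavelength_nm,value
450.0,332.00064132
455.0,282.84912813
460.0,240.96820741
465.0,205.34048212
470.0,176.71001876
475.0,154.86082546
480.0,139.22607539
485.0,129.98896077
490.0,123.16152823
495.0,116.9652029
500.0,112.45183012
505.0,109.54491207
510.0,108.16795088
515.0,114.28330243
520.0,128.51637728
525.0,163.07948402
530.0,208.83911309
535.0,246.32305646
540.0,279.84856858
545.0,279.59172825
550.0,251.86828419
555.0,198.12941498
560.0,176.71001876
565.0,187.41971687
570.0,245.63193495
575.0,291.18316226
580.0,266.0159186
585.0,160.6454716
590.0,74.96788675
595.0,36.57863259
600.0,17.13551697
605.0,11.13482444
610.0,8.03227358
615.0,6.40803178
620.0,5.35484905
625.0,4.49813648
630.0,3.77396427
635.0,3.17087832
640.0,2.67742453
645.0,2.25202653
650.0,1.98129415
655.0,1.85711412
660.0,1.75189769
665.0,1.66725679
670.0,1.6048033
675.0,1.56614915
680.0,1.55290623
685.0,1.55290623
690.0,1.55290623
695.0,1.55290623
700.0,1.55290623
705.0,1.57448415
710.0,1.62829686
715.0,1.69796275
720.0,1.76710019
725.0,1.83344865
730.0,1.90557471
735.0,1.98333745
740.0,2.06659596
745.0,2.15520931
750.0,2.2490366
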