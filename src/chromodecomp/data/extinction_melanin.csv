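wavelength_nm,value
450.0,964.59779466
455.0,929.74956679
460.0,896.5207712
465.0,864.81975661
470.0,834.56096704
475.0,805.66447727
480.0,778.05556814
485.0,751.66433791
490.0,726.42534621
495.0,702.2772876
500.0,679.16269204
505.0,657.02764977
510.0,635.82155834
515.0,615.49688997
520.0,596.00897723
525.0,577.31581562
530.0,559.37788143
535.0,542.15796364
540.0,525.62100869
545.0,509.73397691
550.0,494.46570979
555.0,479.78680702
560.0,465.66951263
565.0,452.08760944
570.0,439.01632115
575.0,426.43222139
580.0,414.3131493
585.0,402.63813104
590.0,391.38730676
595.0,380.54186271
600.0,370.08396788
605.0,359.99671511
610.0,350.26406611
615.0,340.87080011
620.0,331.80246606
625.0,323.04533789
630.0,314.5863727
635.0,306.41317174
640.0,298.51394382
645.0,290.87747111
650.0,283.49307712
655.0,276.35059665
660.0,269.44034766
665.0,262.75310489
670.0,256.28007508
675.0,250.01287371
680.0,243.94350316
685.0,238.06433221
690.0,232.36807671
695.0,226.84778145
700.0,221.49680307
705.0,216.30879399
710.0,211.27768729
715.0,206.39768239
720.0,201.66323163
725.0,197.06902761
730.0,192.60999117
735.0,188.28126017
740.0,184.07817876
745.0,179.99628734
750.0,176.03131304
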