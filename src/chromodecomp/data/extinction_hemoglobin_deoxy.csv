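wavelength_nm,value
450.0,294.51669794
455.0,252.23570229
460.0,214.19396214
465.0,177.86498621
470.0,149.9357735
475.0,133.73623014
480.0,123.16152823
485.0,116.42971799
490.0,112.45183012
495.0,110.57763295
500.0,109.7744056
505.0,111.44779593
510.0,115.12925465
515.0,121.56688568
520.0,131.19380181
525.0,145.2050006
530.0,160.6454716
535.0,173.17227474
540.0,184.74229234
545.0,196.76420465
550.0,206.16168856
555.0,211.28907167
560.0,204.11230188
565.0,187.41971687
570.0,174.03259424
575.0,165.22618062
580.0,147.37525013
585.0,117.80667918
590.0,93.70985844
595.0,73.90972291
600.0,58.90333959
605.0,49.62923424
610.0,42.83879243
615.0,37.3474977
620.0,33.20006413
625.0,30.18951165
630.0,27.70517968
635.0,25.55860787
640.0,23.56133584
645.0,21.66983794
650.0,20.08068395
655.0,18.78405523
660.0,17.62968203
665.0,16.57857037
670.0,15.59172631
675.0,14.63015587
680.0,13.65486509
685.0,12.61483078
690.0,11.56422302
695.0,10.62183771
700.0,9.90647075
705.0,9.37814103
710.0,8.92597942
715.0,8.5624498
720.0,8.30001603
725.0,8.09625992
730.0,7.90712194
735.0,7.74260394
740.0,7.61270782
745.0,7.52743544
750.0,7.49678867
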